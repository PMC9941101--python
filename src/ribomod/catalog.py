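"""References and modification-site catalogs.

Coordinates are 1-based and inclusive on mature molecules throughout the
package; this matches the residue labels used in the rRNA modification
literature (e.g. 18S-Um354 = the uridine at position 354 of mature 18S).
Sequences are held in a canonical ``{A, C, G, U, N}`` alphabet: DNA-style
FASTA input is accepted and ``T`` is normalised to ``U`` on read.

Legacy (pre-revision) residue numbering of human 28S rRNA is *data*, not
arithmetic: the offset between old and new coordinates varies along the
molecule (e.g. 2401 ↔ 2388 but 4042 ↔ 4020), so legacy positions are stored
per site and only ever looked up, never derived.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CatalogError",
    "RnaReference",
    "ModificationSite",
    "SiteCatalog",
    "read_reference",
    "read_site_catalog",
    "write_site_catalog",
    "legacy_lookup",
]

_ALPHABET = frozenset("ACGUN")

CATALOG_COLUMNS = (
    "molecule",
    "position",
    "residue",
    "mod_type",
    "guides",
    "legacy_position",
)


class CatalogError(ValueError):
    """Raised on malformed references or site catalogs."""


def _canonical(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaReference:
    """A named RNA molecule with 1-based coordinates."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise CatalogError(
                f"reference {self.name!r}: illegal characters {sorted(bad)!r} "
                "(expected A/C/G/U/T/N)"
            )
        if not self.sequence:
            raise CatalogError(f"reference {self.name!r} has an empty sequence")

    @classmethod
    def from_raw(cls, name: str, sequence: str) -> "RnaReference":
        """Build from a raw (possibly DNA-alphabet, mixed-case) string."""
        return cls(name=name, sequence=_canonical(sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise CatalogError(
                f"position {position} outside reference {self.name!r} "
                f"(length {self.length})"
            )
        return self.sequence[position - 1]


def read_reference(path) -> dict[str, RnaReference]:
    """Read a FASTA file into an ordered name -> :class:`RnaReference` map.

    Names are the first whitespace-delimited token of each header. Duplicate
    names, empty files and illegal characters are hard failures.
    """
    refs: dict[str, RnaReference] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in refs:
            raise CatalogError(f"duplicate reference name {name!r} in {path}")
        refs[name] = RnaReference.from_raw(name, str(record.seq))
    if not refs:
        raise CatalogError(f"no FASTA records found in {path}")
    return refs


@dataclass(frozen=True)
class ModificationSite:
    """An annotated 2'-O-Me (Nm) or pseudouridine (Psi) position.

    ``guides`` are opaque snoRNA identifiers; an empty tuple means the site
    is an orphan / has no annotated guide ("Unknown" in table exports).
    """

    molecule: str
    position: int
    residue: str
    mod_type: str  # "Nm" | "Psi"
    guides: tuple[str, ...] = ()
    legacy_position: int | None = None

    def __post_init__(self) -> None:
        if self.mod_type not in ("Nm", "Psi"):
            raise CatalogError(
                f"{self.molecule}:{self.position}: unknown mod_type {self.mod_type!r}"
            )
        object.__setattr__(self, "residue", _canonical(self.residue))
        if self.residue not in "ACGU":
            raise CatalogError(
                f"{self.molecule}:{self.position}: residue must be one of A/C/G/U"
            )
        if self.mod_type == "Psi" and self.residue != "U":
            raise CatalogError(
                f"{self.molecule}:{self.position}: Psi annotated on non-U residue "
                f"{self.residue!r}"
            )

    @property
    def label(self) -> str:
        base = {"Nm": f"{self.residue}m", "Psi": "Psi "}[self.mod_type]
        return f"{self.molecule}-{base}{self.position}"

    def validate_against(self, refs: Mapping[str, RnaReference]) -> None:
        if self.molecule not in refs:
            raise CatalogError(f"{self.molecule}:{self.position}: unknown molecule")
        ref = refs[self.molecule]
        if not 1 <= self.position <= ref.length:
            raise CatalogError(
                f"{self.molecule}:{self.position}: outside reference "
                f"(length {ref.length})"
            )
        actual = ref.residue(self.position)
        if actual != self.residue:
            raise CatalogError(
                f"{self.molecule}:{self.position}: catalog residue "
                f"{self.residue!r} != reference residue {actual!r}"
            )


@dataclass(frozen=True)
class SiteCatalog:
    """An ordered, unique collection of modification sites."""

    sites: tuple[ModificationSite, ...]

    def __post_init__(self) -> None:
        keys = [(s.molecule, s.position, s.mod_type) for s in self.sites]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise CatalogError(f"duplicate sites in catalog: {dupes}")
        ordered = tuple(
            sorted(self.sites, key=lambda s: (s.molecule, s.position, s.mod_type))
        )
        object.__setattr__(self, "sites", ordered)

    @classmethod
    def from_sites(
        cls,
        sites: Iterable[ModificationSite],
        refs: Mapping[str, RnaReference] | None = None,
    ) -> "SiteCatalog":
        cat = cls(tuple(sites))
        if refs is not None:
            for site in cat.sites:
                site.validate_against(refs)
        return cat

    @property
    def modality(self) -> str:
        kinds = {s.mod_type for s in self.sites}
        if kinds == {"Nm"}:
            return "Nm"
        if kinds == {"Psi"}:
            return "Psi"
        return "mixed"

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[ModificationSite]:
        return iter(self.sites)

    def molecules(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.molecule, None)
        return tuple(seen)

    def subset(self, mod_type: str | None = None, molecule: str | None = None):
        picked = [
            s
            for s in self.sites
            if (mod_type is None or s.mod_type == mod_type)
            and (molecule is None or s.molecule == molecule)
        ]
        return SiteCatalog(tuple(picked))

    def count(self, molecule: str | None = None, mod_type: str | None = None) -> int:
        return len(self.subset(mod_type=mod_type, molecule=molecule))

    def get(self, molecule: str, position: int, mod_type: str) -> ModificationSite:
        for s in self.sites:
            if (s.molecule, s.position, s.mod_type) == (molecule, position, mod_type):
                return s
        raise CatalogError(f"no {mod_type} site at {molecule}:{position}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "molecule": s.molecule,
                    "position": s.position,
                    "residue": s.residue,
                    "mod_type": s.mod_type,
                    "guides": ";".join(s.guides) if s.guides else "Unknown",
                    "legacy_position": (
                        "" if s.legacy_position is None else str(s.legacy_position)
                    ),
                }
            )
        return pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))


def _parse_guides(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    text = str(raw).strip()
    if not text or text.lower() == "unknown":
        return ()
    return tuple(g.strip() for g in text.split(";") if g.strip())


def read_site_catalog(path, refs: Mapping[str, RnaReference]) -> SiteCatalog:
    """Read a tab-separated site catalog and validate it against references.

    Expected columns: ``molecule  position  residue  mod_type  guides
    legacy_position`` (guides ";"-separated, "Unknown"/blank = orphan;
    legacy_position may be blank).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = set(CATALOG_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise CatalogError(f"{path}: missing catalog columns {sorted(missing)}")
    sites = []
    for _, row in df.iterrows():
        legacy = row.get("legacy_position", "")
        legacy_val = int(legacy) if str(legacy).strip() else None
        site = ModificationSite(
            molecule=row["molecule"].strip(),
            position=int(row["position"]),
            residue=row["residue"].strip(),
            mod_type=row["mod_type"].strip(),
            guides=_parse_guides(row.get("guides", "")),
            legacy_position=legacy_val,
        )
        sites.append(site)
    return SiteCatalog.from_sites(sites, refs=refs)


def write_site_catalog(catalog: SiteCatalog, path) -> None:
    """Write a catalog in the same TSV dialect :func:`read_site_catalog` reads."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def legacy_lookup(catalog: SiteCatalog, molecule: str, legacy_position: int) -> ModificationSite:
    """Return the unique site of ``molecule`` carrying this legacy number."""
    hits = [
        s
        for s in catalog
        if s.molecule == molecule and s.legacy_position == legacy_position
    ]
    if not hits:
        raise CatalogError(
            f"no site on {molecule} with legacy position {legacy_position}"
        )
    if len(hits) > 1:
        raise CatalogError(
            f"ambiguous legacy position {legacy_position} on {molecule}: "
            f"{[s.position for s in hits]}"
        )
    return hits[0]
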