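"""Packaged synthetic fixtures: references, catalogs, demo ground truths.

Everything here is generated deterministically in code (fixed internal seed)
so the package ships no data files. The fixture set mirrors the shape of the
human rRNA modification landscape:

* three molecules (18S, 28S, 5.8S) with realistic mature lengths;
* a 2'-O-Me catalog of 41 / 67 / 2 sites and a pseudouridine catalog of
  44 / 61 / 2 sites on 18S / 28S / 5.8S respectively, including the named
  FUS-responsive sites (18S-Um354, 18S-Cm1272, 28S-Am2401, 28S-Psi1779, ...)
  with their guide snoRNAs and, on 28S, legacy residue numbers;
* demo ground-truth stoichiometries for a wild-type vs FUS-knockout
  contrast, using the published sub-stoichiometric values at the named
  sites and near-saturated defaults elsewhere;
* a fabricated snoRNA differential-expression table in DESeq2-export shape.

The sequences are random-composition RNA except that every pseudouridine
site is embedded in a uridine run (+/- 7 nt). HydraPsiSeq protection scoring
normalises a U's 5'-end count to the plain local window mean, which is only
calibrated (NormUcount ~ 1 at an unmodified U) where the window background
is dominated by unmodified-U cleavage; the U-rich context makes the fixture
a valid substrate for that score. Real mixed-composition neighbourhoods
shift PsiScore downward uniformly — the origin of strongly negative scores
at unprotected residues.

Note: the bundled 2'-O-Me catalog totals 110 sites while published
whole-catalog tallies of highly methylated positions count 109; the fixture
ships the per-molecule counts as annotated per modality and does not try to
reconcile the two tallies.
"""

from __future__ import annotations

import functools
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ModificationSite, RnaReference, SiteCatalog

__all__ = [
    "FIXTURE_SEED",
    "REF_LENGTHS",
    "HEK293T_NM_STOICHIOMETRY",
    "HEK293T_PSI_STOICHIOMETRY",
    "SHSY5Y_DIFF_NM_STOICHIOMETRY",
    "DEMO_CONDITIONS",
    "demo_references",
    "demo_nm_catalog",
    "demo_psi_catalog",
    "demo_truth_fractions",
    "demo_de_table",
    "poly_u_reference",
    "write_demo_inputs",
]

FIXTURE_SEED = 20230220  # fixture identity; changing it changes the fixture set
REF_LENGTHS = {"18S": 1869, "28S": 5070, "5.8S": 157}

DEMO_CONDITIONS = ("WT", "FUS_KO")

# Named 2'-O-Me sites: position, residue, guides (";"-joined), legacy position.
_NM_NAMED = {
    "18S": [
        (354, "U", "SNORD90", None),
        (436, "G", "SNORD100", None),
        (576, "A", "SNORD93", None),
        (867, "G", "SNORD98", None),
        (951, "C", "SNORD114-3", None),
        (995, "G", "SNORD53", None),
        (1000, "C", "SNORD44", None),
        (1034, "A", "SNORD59A", None),
        (1272, "C", "SNORD66", None),
        (1440, "C", "SNORD125", None),
        (1639, "G", "SNORD81", None),
    ],
    "28S": [
        (1323, "A", "SNORD126", 1310),
        (1881, "C", "SNORD48", 1868),
        (2075, "C", "SNORD114-14", None),
        (2401, "A", "SNORD68", 2388),
        (2787, "A", "SNORD99", 2774),
        (2861, "C", "SNORD50A;SNORD50B", 2848),
        (2876, "G", "SNORD50A;SNORD50B", 2863),
        (3867, "A", "SNORD92", 3846),
        (4042, "G", "SNORD102", 4020),
        (4456, "C", "SNORD49A;SNORD49B", 4426),
    ],
    "5.8S": [
        (14, "U", "", None),
    ],
}

# Named pseudouridine sites: position, guides, legacy position.
_PSI_NAMED = {
    "18S": [
        (296, "", None),
        (681, "", None),
        (897, "SNORA44", None),
        (1046, "", None),
    ],
    "28S": [
        (1536, "", None),
        (1582, "SNORA7A;SNORA7B", 1569),
        (1779, "SNORA47", 1766),
        (2839, "", 2826),
        (2843, "", 2830),
        (3734, "SNORA31", 3713),
        (3822, "SNORA54", 3801),
        (3884, "", None),
        (4312, "SNORA2A;SNORA2B", 4282),
        (4420, "SNORA63", 4390),
        (4579, "", 4549),
        (4636, "SNORA81", 4606),
        (4673, "SNORA30;SNORA37", 4643),
        (4973, "SNORA43", 4938),
        (5001, "SNORA22;SNORA33", 4966),
    ],
    "5.8S": [],
}

_NM_TOTALS = {"18S": 41, "28S": 67, "5.8S": 2}
_PSI_TOTALS = {"18S": 44, "28S": 61, "5.8S": 2}

_PSI_U_CONTEXT = 7  # nt of forced U on each side of a Psi site
_MIN_SITE_SPACING = 13  # keeps scoring windows and U contexts disjoint

# Demo ground truths at the named sites, (WT, FUS_KO) modified fraction.
HEK293T_NM_STOICHIOMETRY = {
    ("18S", 354): (0.02, 0.31),
    ("18S", 576): (0.57, 0.64),
    ("18S", 867): (0.76, 0.82),
    ("18S", 951): (0.34, 0.01),
    ("18S", 1000): (0.29, 0.14),
    ("18S", 1272): (0.39, 0.60),
    ("18S", 1639): (0.62, 0.49),
    ("28S", 2075): (0.21, 0.04),
    ("28S", 2401): (0.76, 0.87),
    ("28S", 2861): (0.64, 0.79),
    ("28S", 2876): (0.37, 0.54),
    ("28S", 4042): (0.46, 0.63),
}

HEK293T_PSI_STOICHIOMETRY = {
    ("28S", 1582): (0.68, 0.77),
    ("28S", 1779): (0.75, 0.92),
    ("28S", 2839): (0.17, 0.29),
    ("28S", 2843): (0.00, 0.00),  # unprotected residue; negative printed score
    ("28S", 3734): (0.86, 0.92),
    ("28S", 3822): (0.72, 0.85),
    ("28S", 4312): (0.85, 0.91),
    ("28S", 4420): (0.56, 0.72),
    ("28S", 4579): (0.41, 0.32),
    ("28S", 4673): (0.65, 0.79),
    ("28S", 5001): (0.59, 0.77),
}

# Differentiated-neuroblastoma demo contrast (used for the Cm2075 drop).
SHSY5Y_DIFF_NM_STOICHIOMETRY = {
    ("18S", 354): (0.59, 0.71),
    ("18S", 436): (0.61, 0.74),
    ("18S", 1272): (0.69, 0.81),
    ("28S", 2075): (0.16, 0.01),
}

_DEFAULT_NM_FRACTION = 0.95  # near-saturated background site
_DEFAULT_PSI_FRACTION = 0.90


def _parse_guides(raw: str) -> tuple[str, ...]:
    return tuple(g for g in raw.split(";") if g) if raw else ()


def _pick_fillers(rng, length: int, occupied: list[int], n: int) -> list[int]:
    """Deterministic greedy placement with minimum spacing to all sites."""
    candidates = np.arange(10, length - 9)
    rng.shuffle(candidates)
    chosen: list[int] = []
    taken = list(occupied)
    for pos in candidates:
        if all(abs(int(pos) - t) >= _MIN_SITE_SPACING for t in taken):
            chosen.append(int(pos))
            taken.append(int(pos))
            if len(chosen) == n:
                return sorted(chosen)
    raise RuntimeError(f"could not place {n} filler sites on length {length}")


@functools.lru_cache(maxsize=1)
def _build_fixture():
    refs: dict[str, RnaReference] = {}
    nm_sites: list[ModificationSite] = []
    psi_sites: list[ModificationSite] = []
    for mol_index, (molecule, length) in enumerate(REF_LENGTHS.items()):
        rng = np.random.default_rng([FIXTURE_SEED, mol_index])
        seq = rng.choice(list("ACGU"), size=length)

        nm_named = _NM_NAMED[molecule]
        psi_named = _PSI_NAMED[molecule]
        named_positions = [p for p, *_ in nm_named] + [p for p, *_ in psi_named]

        n_nm_fill = _NM_TOTALS[molecule] - len(nm_named)
        n_psi_fill = _PSI_TOTALS[molecule] - len(psi_named)
        fillers = _pick_fillers(
            rng, length, named_positions, n_nm_fill + n_psi_fill
        )
        nm_fill, psi_fill = fillers[:n_nm_fill], fillers[n_nm_fill:]

        for pos, residue, *_ in nm_named:
            seq[pos - 1] = residue
        psi_positions = [p for p, *_ in psi_named] + psi_fill
        for pos in psi_positions:  # U-rich context keeps the background calibrated
            lo = max(pos - _PSI_U_CONTEXT, 1)
            hi = min(pos + _PSI_U_CONTEXT, length)
            seq[lo - 1 : hi] = "U"

        sequence = "".join(seq)
        ref = RnaReference(name=molecule, sequence=sequence)
        refs[molecule] = ref

        for pos, residue, guides, legacy in nm_named:
            nm_sites.append(
                ModificationSite(
                    molecule, pos, residue, "Nm", _parse_guides(guides), legacy
                )
            )
        for pos in nm_fill:
            nm_sites.append(
                ModificationSite(molecule, pos, ref.residue(pos), "Nm", (), None)
            )
        for pos, guides, legacy in psi_named:
            psi_sites.append(
                ModificationSite(molecule, pos, "U", "Psi", _parse_guides(guides), legacy)
            )
        for pos in psi_fill:
            psi_sites.append(ModificationSite(molecule, pos, "U", "Psi", (), None))

    nm_catalog = SiteCatalog.from_sites(nm_sites, refs=refs)
    psi_catalog = SiteCatalog.from_sites(psi_sites, refs=refs)
    return refs, nm_catalog, psi_catalog


def demo_references() -> dict[str, RnaReference]:
    """The packaged synthetic 18S / 28S / 5.8S references."""
    return dict(_build_fixture()[0])


def demo_nm_catalog() -> SiteCatalog:
    """The packaged 2'-O-Me catalog (41 + 67 + 2 sites)."""
    return _build_fixture()[1]


def demo_psi_catalog() -> SiteCatalog:
    """The packaged pseudouridine catalog (44 + 61 + 2 sites)."""
    return _build_fixture()[2]


def demo_truth_fractions(
    condition: str,
    mod_type: str,
    stoichiometries: dict | None = None,
) -> dict[str, dict[int, float]]:
    """Ground-truth modified fraction per molecule for one demo condition.

    Catalog sites without a named demo value sit at a near-saturated default
    (0.95 for Nm, 0.90 for Psi), mimicking the stability of most positions.
    """
    if condition not in DEMO_CONDITIONS:
        raise ValueError(f"unknown demo condition {condition!r}; use {DEMO_CONDITIONS}")
    cond_index = DEMO_CONDITIONS.index(condition)
    if stoichiometries is None:
        stoichiometries = (
            HEK293T_NM_STOICHIOMETRY if mod_type == "Nm" else HEK293T_PSI_STOICHIOMETRY
        )
    default = _DEFAULT_NM_FRACTION if mod_type == "Nm" else _DEFAULT_PSI_FRACTION
    catalog = demo_nm_catalog() if mod_type == "Nm" else demo_psi_catalog()
    fractions: dict[str, dict[int, float]] = {}
    for site in catalog:
        value = stoichiometries.get((site.molecule, site.position))
        f = default if value is None else value[cond_index]
        fractions.setdefault(site.molecule, {})[site.position] = f
    return fractions


def demo_de_table() -> pd.DataFrame:
    """Fabricated guide snoRNA differential-expression table (alt vs ref).

    log2fc / padj values are synthetic but chosen so that the guides of the
    FUS-responsive demo sites move co-directionally with them, including the
    two-guide sites where only one guide responds.
    """
    rows = [
        # guide, log2fc, padj, source
        ("SNORD90", 1.20, 0.001, "smallRNAseq"),
        ("SNORD90", 1.05, 0.010, "qPCR"),
        ("SNORD66", 0.90, 0.004, "smallRNAseq"),
        ("SNORD100", 0.85, 0.008, "smallRNAseq"),
        ("SNORD68", 0.60, 0.030, "smallRNAseq"),
        ("SNORD50A", 0.80, 0.010, "smallRNAseq"),
        ("SNORD50B", 0.10, 0.600, "smallRNAseq"),
        ("SNORD102", 0.50, 0.040, "smallRNAseq"),
        ("SNORD93", 0.30, 0.200, "smallRNAseq"),
        ("SNORD98", 0.20, 0.300, "smallRNAseq"),
        ("SNORD126", -0.90, 0.010, "smallRNAseq"),
        ("SNORD114-14", -1.30, 0.002, "smallRNAseq"),
        ("SNORD114-3", -0.70, 0.020, "smallRNAseq"),
        ("SNORD44", -0.80, 0.015, "qPCR"),
        ("SNORD81", -0.40, 0.120, "smallRNAseq"),
        ("SNORA47", 1.10, 0.0005, "smallRNAseq"),
        ("SNORA7A", 0.60, 0.020, "smallRNAseq"),
        ("SNORA7B", 0.05, 0.900, "smallRNAseq"),
        ("SNORA31", 0.40, 0.040, "smallRNAseq"),
        ("SNORA54", 0.50, 0.030, "smallRNAseq"),
        ("SNORA2A", 0.45, 0.045, "smallRNAseq"),
        ("SNORA2B", 0.00, 0.950, "smallRNAseq"),
        ("SNORA63", 0.70, 0.010, "smallRNAseq"),
        ("SNORA81", -0.55, 0.025, "smallRNAseq"),
        ("SNORA30", 0.05, 0.800, "smallRNAseq"),
        ("SNORA37", 0.90, 0.002, "smallRNAseq"),
        ("SNORA22", -0.10, 0.700, "smallRNAseq"),
        ("SNORA33", 0.80, 0.004, "smallRNAseq"),
        ("SNORA44", 0.65, 0.018, "qPCR"),
        ("SNORA43", 0.35, 0.150, "smallRNAseq"),
    ]
    return pd.DataFrame(rows, columns=["snorna", "log2fc", "padj", "source"])


def poly_u_reference(length: int = 120, name: str = "polyU") -> RnaReference:
    """An all-uridine substrate: the idealised protection-scoring context."""
    return RnaReference(name=name, sequence="U" * length)


def write_demo_inputs(directory) -> dict[str, Path]:
    """Materialise the fixture set as plain files; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = directory / "references.fasta"
    with open(fasta, "w") as fh:
        for ref in demo_references().values():
            fh.write(f">{ref.name} synthetic demo reference\n")
            for i in range(0, ref.length, 70):
                fh.write(ref.sequence[i : i + 70] + "\n")
    paths["reference_fasta"] = fasta

    from .catalog import write_site_catalog  # local import avoids cycle at module load

    nm_path = directory / "nm_catalog.tsv"
    write_site_catalog(demo_nm_catalog(), nm_path)
    paths["nm_catalog"] = nm_path
    psi_path = directory / "psi_catalog.tsv"
    write_site_catalog(demo_psi_catalog(), psi_path)
    paths["psi_catalog"] = psi_path

    for condition in DEMO_CONDITIONS:
        for mod_type in ("Nm", "Psi"):
            truth_path = directory / f"truth_{condition}_{mod_type}.tsv"
            with open(truth_path, "w") as fh:
                fh.write("molecule\tposition\tfraction\n")
                fractions = demo_truth_fractions(condition, mod_type)
                for molecule in sorted(fractions):
                    for pos in sorted(fractions[molecule]):
                        fh.write(f"{molecule}\t{pos}\t{fractions[molecule][pos]}\n")
            paths[f"truth_{condition}_{mod_type}"] = truth_path

    de_path = directory / "snorna_de.tsv"
    demo_de_table().to_csv(de_path, sep="\t", index=False)
    paths["de_table"] = de_path
    return paths
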