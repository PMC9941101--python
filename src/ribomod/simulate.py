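"""Synthetic cleavage-library profiles with known ground-truth stoichiometry.

Two chemistries are emulated at the level of per-position cleavage *events*
rather than individual molecules:

* **RMS** (alkaline hydrolysis): every phosphodiester bond is attacked with a
  uniform propensity; a 2'-O-methyl on nucleotide *j* protects the bond 3' of
  *j*, scaling its expected cleavage by ``1 - f_j * (1 - residual)`` where
  ``f_j`` is the methylated fraction. Each event leaves a 3' read end at *j*
  and a 5' read end at *j + 1*.
* **HydraPsi** (hydrazine/aniline): only uridines are cleaved appreciably;
  pseudouridine protects its own residue. Non-U residues retain a small
  relative propensity ``bg_rate``. Each event leaves a 5' read end at the
  cleaved U (plus a configurable ``end_offset``).

Event counts per bond/residue are independent Poisson draws — cleavage at
distinct bonds is rare per molecule copy and the downstream scores are local
count ratios, so molecule-level bookkeeping would change nothing they can
see. An optional fragment mode (RMS) draws whole 20-40 nt fragments instead
and exists to exercise end-count conservation.

Replicate ``r`` of a run seeded with ``s`` uses the independent stream
``default_rng([s, r])``; adding replicates never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import RnaReference

__all__ = [
    "SimulationError",
    "TruthProfile",
    "ProtocolParams",
    "EndCountProfile",
    "simulate_rms",
    "simulate_hydrapsi",
    "write_profile",
    "read_profile",
]

RMS = "RMS"
HYDRAPSI = "HydraPsi"


class SimulationError(ValueError):
    """Raised on invalid simulation inputs or malformed profile files."""


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth modified fraction per position for one molecule."""

    molecule: str
    fractions: Mapping[int, float]
    mod_type: str  # "Nm" | "Psi"

    def __post_init__(self) -> None:
        if self.mod_type not in ("Nm", "Psi"):
            raise SimulationError(f"unknown mod_type {self.mod_type!r}")
        for pos, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(
                    f"{self.molecule}:{pos}: fraction {f} outside [0, 1]"
                )

    def validate_against(self, ref: RnaReference) -> None:
        if ref.name != self.molecule:
            raise SimulationError(
                f"truth is for {self.molecule!r}, reference is {ref.name!r}"
            )
        for pos in self.fractions:
            if not 1 <= pos <= ref.length:
                raise SimulationError(
                    f"{self.molecule}:{pos}: outside reference (length {ref.length})"
                )
            if self.mod_type == "Psi" and ref.residue(pos) != "U":
                raise SimulationError(
                    f"{self.molecule}:{pos}: Psi truth on non-U residue "
                    f"{ref.residue(pos)!r}"
                )


@dataclass(frozen=True)
class ProtocolParams:
    """Simulation parameters for one chemistry.

    depth * base_rate is the expected cleavage-event count at a fully
    unprotected bond (RMS) or uridine (HydraPsi). ``residual`` is the
    relative propensity retained at a fully modified site (0 = complete
    protection); ``bg_rate`` (HydraPsi only) the relative propensity at
    non-U residues; ``end_offset`` shifts the reported 5' end of a
    hydrazine/aniline cleavage relative to the cleaved U.
    """

    protocol: str
    depth: float
    base_rate: float = 1.0
    residual: float = 0.0
    bg_rate: float = 0.01
    frag_min: int = 20
    frag_max: int = 40
    end_offset: int = 0
    fragment_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in (RMS, HYDRAPSI):
            raise SimulationError(f"unknown protocol {self.protocol!r}")
        if self.depth <= 0:
            raise SimulationError("depth must be > 0")
        if self.base_rate <= 0:
            raise SimulationError("base_rate must be > 0")
        if not 0.0 <= self.residual <= 1.0:
            raise SimulationError(
                f"residual {self.residual} outside [0, 1]; hyper-reactive sites "
                "are outside the protection model"
            )
        if self.bg_rate < 0:
            raise SimulationError("bg_rate must be >= 0")
        if self.frag_min > self.frag_max or self.frag_min < 1:
            raise SimulationError("require 1 <= frag_min <= frag_max")
        if self.fragment_mode and self.protocol != RMS:
            raise SimulationError("fragment mode applies to the RMS protocol only")


@dataclass(frozen=True)
class EndCountProfile:
    """Per-position 5'/3' read-end counts for one replicate of one protocol.

    ``counts5[p - 1]`` / ``counts3[p - 1]`` hold the counts at the 1-based
    position ``p``.
    """

    molecule: str
    counts5: np.ndarray
    counts3: np.ndarray
    replicate_id: str
    protocol: str

    def __post_init__(self) -> None:
        c5 = np.asarray(self.counts5, dtype=np.int64)
        c3 = np.asarray(self.counts3, dtype=np.int64)
        if c5.ndim != 1 or c3.shape != c5.shape:
            raise SimulationError("counts5/counts3 must be 1-D vectors of equal length")
        if c5.size == 0:
            raise SimulationError("empty profile (length 0)")
        if (c5 < 0).any() or (c3 < 0).any():
            raise SimulationError("read-end counts must be non-negative")
        object.__setattr__(self, "counts5", c5)
        object.__setattr__(self, "counts3", c3)

    @property
    def length(self) -> int:
        return int(self.counts5.size)


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # Independent stream per replicate; stable under added replicates.
    return np.random.default_rng([int(seed), int(replicate_index)])


def _fraction_vector(truth: TruthProfile, length: int) -> np.ndarray:
    f = np.zeros(length, dtype=float)
    for pos, frac in truth.fractions.items():
        f[pos - 1] = frac
    return f


def rms_bond_intensity(
    ref: RnaReference, truth: TruthProfile, params: ProtocolParams
) -> np.ndarray:
    """Expected cleavage events per bond (bond j = 3' of nucleotide j)."""
    f = _fraction_vector(truth, ref.length)[:-1]  # bonds 1..L-1 follow nucleotide j
    return params.depth * params.base_rate * (1.0 - f * (1.0 - params.residual))


def simulate_rms(
    ref: RnaReference,
    truth: TruthProfile,
    params: ProtocolParams,
    n_replicates: int,
) -> list[EndCountProfile]:
    """Simulate alkaline-hydrolysis end-count profiles with Nm protection."""
    if truth.mod_type != "Nm":
        raise SimulationError("simulate_rms requires an Nm truth profile")
    if params.protocol != RMS:
        raise SimulationError("simulate_rms requires params.protocol == 'RMS'")
    truth.validate_against(ref)
    if ref.length < 2:
        raise SimulationError("RMS needs a molecule with at least one bond")
    lam = rms_bond_intensity(ref, truth, params)
    profiles = []
    for r in range(n_replicates):
        rng = _replicate_rng(params.seed, r)
        counts5 = np.zeros(ref.length, dtype=np.int64)
        counts3 = np.zeros(ref.length, dtype=np.int64)
        if params.fragment_mode:
            _simulate_rms_fragments(rng, lam, params, counts5, counts3)
        else:
            events = rng.poisson(lam)
            counts3[: ref.length - 1] += events  # 3' end at nucleotide j
            counts5[1:] += events  # 5' end at nucleotide j+1
        profiles.append(
            EndCountProfile(
                molecule=ref.name,
                counts5=counts5,
                counts3=counts3,
                replicate_id=f"rep{r + 1}",
                protocol=RMS,
            )
        )
    return profiles


def _simulate_rms_fragments(rng, lam, params, counts5, counts3) -> None:
    """Draw whole fragments bounded by two cleavage events 20-40 nt apart."""
    # A fragment bounded by cuts at bonds j1 < j2 spans nucleotides j1+1..j2,
    # so its 5' end sits at j1+1 and its 3' end at j2 (both 1-based).
    n_bonds = lam.size
    weights = lam / lam.sum()
    n_fragments = rng.poisson(params.depth)
    j1 = rng.choice(n_bonds, size=n_fragments, p=weights) + 1  # 1-based 5' bond
    lengths = rng.integers(params.frag_min, params.frag_max + 1, size=n_fragments)
    j2 = j1 + lengths
    keep = j2 <= n_bonds  # the 3' cut must land on a real bond
    np.add.at(counts5, j1[keep], 1)  # nucleotide j1+1 has 0-based index j1
    np.add.at(counts3, j2[keep] - 1, 1)  # nucleotide j2 has 0-based index j2-1


def hydrapsi_site_intensity(
    ref: RnaReference, truth: TruthProfile, params: ProtocolParams
) -> np.ndarray:
    """Expected cleavage events per residue under hydrazine/aniline."""
    f = _fraction_vector(truth, ref.length)
    base = params.depth * params.base_rate
    is_u = np.frombuffer(ref.sequence.encode(), dtype="S1") == b"U"
    lam = np.where(is_u, base * (1.0 - f * (1.0 - params.residual)), base * params.bg_rate)
    return lam


def simulate_hydrapsi(
    ref: RnaReference,
    truth: TruthProfile,
    params: ProtocolParams,
    n_replicates: int,
) -> list[EndCountProfile]:
    """Simulate hydrazine/aniline 5'-end profiles with Psi protection."""
    if truth.mod_type != "Psi":
        raise SimulationError("simulate_hydrapsi requires a Psi truth profile")
    if params.protocol != HYDRAPSI:
        raise SimulationError("simulate_hydrapsi requires params.protocol == 'HydraPsi'")
    truth.validate_against(ref)
    lam = hydrapsi_site_intensity(ref, truth, params)
    profiles = []
    for r in range(n_replicates):
        rng = _replicate_rng(params.seed, r)
        events = rng.poisson(lam)
        counts5 = np.zeros(ref.length, dtype=np.int64)
        if params.end_offset == 0:
            counts5 += events
        else:
            idx = np.arange(ref.length) + params.end_offset
            ok = (idx >= 0) & (idx < ref.length)
            np.add.at(counts5, idx[ok], events[ok])
        profiles.append(
            EndCountProfile(
                molecule=ref.name,
                counts5=counts5,
                counts3=np.zeros(ref.length, dtype=np.int64),
                replicate_id=f"rep{r + 1}",
                protocol=HYDRAPSI,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Profile TSV round trip


def write_profile(profile: EndCountProfile, path, seed: int | None = None) -> None:
    """Write ``position  count5  count3`` TSV with metadata header comments."""
    with open(path, "w") as fh:
        fh.write(f"# molecule={profile.molecule}\n")
        fh.write(f"# protocol={profile.protocol}\n")
        fh.write(f"# replicate_id={profile.replicate_id}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("position\tcount5\tcount3\n")
        for p in range(1, profile.length + 1):
            fh.write(f"{p}\t{profile.counts5[p - 1]}\t{profile.counts3[p - 1]}\n")


def read_profile(path) -> EndCountProfile:
    """Read a profile written by :func:`write_profile` (lossless round trip)."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.split("\t") != ["position", "count5", "count3"]:
                    raise SimulationError(f"{path}:{lineno}: bad profile header {line!r}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SimulationError(f"{path}:{lineno}: malformed line {line!r}")
            try:
                pos, c5, c3 = (int(x) for x in parts)
            except ValueError as exc:
                raise SimulationError(f"{path}:{lineno}: non-integer field") from exc
            if c5 < 0 or c3 < 0:
                raise SimulationError(f"{path}:{lineno}: negative count")
            rows.append((pos, c5, c3))
    if not rows:
        raise SimulationError(f"{path}: empty profile")
    rows.sort()
    positions = [r[0] for r in rows]
    if positions != list(range(1, len(rows) + 1)):
        raise SimulationError(f"{path}: positions must be 1..L without gaps")
    for key in ("molecule", "protocol", "replicate_id"):
        if key not in meta:
            raise SimulationError(f"{path}: missing '# {key}=' header")
    return EndCountProfile(
        molecule=meta["molecule"],
        counts5=np.array([r[1] for r in rows], dtype=np.int64),
        counts3=np.array([r[2] for r in rows], dtype=np.int64),
        replicate_id=meta["replicate_id"],
        protocol=meta["protocol"],
    )


def write_bedgraph(profile: EndCountProfile, path, which: str = "counts5") -> None:
    """Export one end-count vector as BEDGraph (0-based, half-open)."""
    counts = getattr(profile, which)
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{profile.molecule}_{profile.replicate_id}_{which}"\n'
        )
        for p in range(1, profile.length + 1):
            c = counts[p - 1]
            if c:
                fh.write(f"{profile.molecule}\t{p - 1}\t{p}\t{c}\n")
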