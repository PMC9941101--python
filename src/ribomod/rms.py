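"""MethScore: 2'-O-methylation stoichiometry from read-end drop-off.

A 2'-O-methyl on nucleotide *i* protects the phosphodiester bond 3' of *i*
from alkaline attack, so cleavage evidence at bond *i* drops in proportion
to the methylated fraction. The per-bond evidence combines both read ends a
cleavage produces (the 3' end at *i* and the 5' end at *i + 1*), which makes
the track robust to one-sided end losses. The score compares bond *i* to the
mean of up to six flanking bonds per side:

    MethScore_i = clip(1 - 2 * c_i / (Lbar + Rbar), 0, 1)

which equals the methylated fraction in expectation when flanking bonds are
cleaved at the background rate. A score is *undefined* (never 0) when fewer
than three bonds are available on either side or the flanking background is
zero — a molecule end must not masquerade as an unmethylated site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import SiteCatalog
from .simulate import RMS, EndCountProfile

__all__ = [
    "ScoringError",
    "CleavageTrack",
    "build_cleavage_track",
    "methscore",
    "score_catalog_rms",
]

SCORE_COLUMNS = (
    "molecule",
    "position",
    "residue",
    "mod_type",
    "replicate",
    "score",
    "local_coverage",
)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageTrack:
    """Combined cleavage evidence per bond; ``c[j - 1]`` is bond ``j``."""

    molecule: str
    c: np.ndarray
    source_replicate: str

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        if c.ndim != 1 or c.size < 1:
            raise ScoringError("cleavage track must be a non-empty 1-D vector")
        if (c < 0).any():
            raise ScoringError("cleavage evidence must be non-negative")
        object.__setattr__(self, "c", c)

    @property
    def n_bonds(self) -> int:
        return int(self.c.size)


def build_cleavage_track(profile: EndCountProfile) -> CleavageTrack:
    """c[j] = counts3[j] + counts5[j + 1] for bonds j = 1..L-1."""
    if profile.protocol != RMS:
        raise ScoringError(
            f"cleavage tracks are defined for RMS profiles, got {profile.protocol!r}"
        )
    if profile.length < 2:
        raise ScoringError("profile too short to contain a bond")
    c = profile.counts3[:-1] + profile.counts5[1:]
    return CleavageTrack(
        molecule=profile.molecule, c=c, source_replicate=profile.replicate_id
    )


def _score_at(track: CleavageTrack, position: int, flank: int):
    """Return (score, local_coverage); both None/nan when undefined."""
    i = position  # site at nucleotide i maps to bond i
    nb = track.n_bonds
    if not 1 <= i <= nb:
        raise ScoringError(
            f"{track.molecule}: position {position} has no bond (1..{nb})"
        )
    if flank < 1:
        raise ScoringError("flank must be >= 1")
    left = track.c[max(i - flank, 1) - 1 : i - 1]
    right = track.c[i : min(i + flank, nb)]
    if left.size < 3 or right.size < 3:
        return None, float("nan")
    lbar = float(left.mean())
    rbar = float(right.mean())
    coverage = 0.5 * (lbar + rbar)
    if lbar + rbar == 0:
        return None, coverage
    raw = 1.0 - 2.0 * float(track.c[i - 1]) / (lbar + rbar)
    return float(np.clip(raw, 0.0, 1.0)), coverage


def methscore(track: CleavageTrack, position: int, flank: int = 6):
    """MethScore at a site, or ``None`` when the window is unusable."""
    score, _ = _score_at(track, position, flank)
    return score


def score_catalog_rms(
    profiles: Sequence[EndCountProfile],
    catalog: SiteCatalog,
    flank: int = 6,
) -> pd.DataFrame:
    """Score every catalog site in every replicate profile.

    Returns a long table (one row per site x replicate) with ``score`` NaN
    where the window was unusable; missing scores are warned about and are
    excluded from downstream means.
    """
    if not profiles:
        raise ScoringError("at least one replicate profile is required")
    by_molecule: dict[str, list[EndCountProfile]] = {}
    for p in profiles:
        by_molecule.setdefault(p.molecule, []).append(p)
    missing = [m for m in catalog.molecules() if m not in by_molecule]
    if missing:
        raise ScoringError(f"no profiles supplied for catalog molecules {missing}")

    rows = []
    for molecule in catalog.molecules():
        tracks = [build_cleavage_track(p) for p in by_molecule[molecule]]
        for site in catalog.subset(molecule=molecule):
            if site.mod_type != "Nm":
                raise ScoringError(
                    f"{site.label}: MethScore applies to Nm sites only"
                )
            for track in tracks:
                score, coverage = _score_at(track, site.position, flank)
                if score is None:
                    warnings.warn(
                        f"{site.label} ({track.source_replicate}): MethScore "
                        "undefined (truncated window or zero background)",
                        stacklevel=2,
                    )
                rows.append(
                    {
                        "molecule": site.molecule,
                        "position": site.position,
                        "residue": site.residue,
                        "mod_type": site.mod_type,
                        "replicate": track.source_replicate,
                        "score": np.nan if score is None else score,
                        "local_coverage": coverage,
                    }
                )
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
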