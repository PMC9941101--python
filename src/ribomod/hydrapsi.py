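"""PsiScore: pseudouridine protection from hydrazine/aniline 5'-end profiles.

Hydrazine attacks uridine; aniline then cleaves the backbone, so 5' read-end
counts pile up at reactive (unmodified) uridines while pseudouridine resists
the chemistry. Scoring proceeds in three steps:

1. ``rolling_background`` — a plain mean of the 5'-end counts over a 10-nt
   window (center-right for the even default) normalises away local coverage
   trends; with ``exclude_self`` the queried position is left out of its own
   background (leave-one-out).
2. ``NormUcount`` — the position's count divided by that background. This is
   the protection value: ~1 at a background-level uridine, ~0 at a fully
   protected one, > 1 at hyper-reactive residues.
3. ``PsiScore = 1 - NormUcount`` on the U-only profile. The score is bounded
   above by 1 but deliberately NOT floored below 0: a negative score means
   the residue is cleaved above its local background, i.e. it is not
   pseudouridylated.

The absolute calibration of NormUcount assumes the window background is
dominated by unmodified-U cleavage; where non-U neighbours dilute the
background the score shifts down uniformly, which is exactly how strongly
negative printed scores at unprotected residues arise. ``scoremean`` is an
auxiliary flanking-ratio diagnostic computed on the nearest U neighbours
(same shape as the RMS score, clipped only from above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RnaReference, SiteCatalog
from .rms import ScoringError
from .simulate import HYDRAPSI, EndCountProfile

__all__ = [
    "UProtectionTrack",
    "rolling_background",
    "norm_ucount",
    "build_protection_track",
    "u_profile",
    "psiscore",
    "scoremean",
    "score_catalog_psi",
]

PSI_SCORE_COLUMNS = (
    "molecule",
    "position",
    "residue",
    "mod_type",
    "replicate",
    "score",
    "scoremean",
    "local_coverage",
)


def rolling_background(
    counts5: np.ndarray, window: int = 10, exclude_self: bool = False
) -> np.ndarray:
    """Local background: windowed mean of 5'-end counts, NaN where unusable.

    The window of ``window`` positions is centred at each position
    (center-right for even windows: ``i - window//2 .. i + window//2 - 1``)
    and shrinks at molecule ends. Background is missing where the clipped
    window holds fewer than ``window / 2`` positions or its mean is zero.
    """
    if window < 2:
        raise ScoringError("background window must be >= 2")
    counts = np.asarray(counts5, dtype=float)
    L = counts.size
    pos = np.arange(1, L + 1)
    lo = np.maximum(pos - window // 2, 1)
    hi = np.minimum(pos + (window - window // 2) - 1, L)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    n = (hi - lo + 1).astype(float)
    total = csum[hi] - csum[lo - 1]
    usable = n >= window / 2.0
    if exclude_self:
        total = total - counts
        n = n - 1.0
        usable &= n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        bg = np.where(usable, total / np.maximum(n, 1.0), np.nan)
    bg[~usable] = np.nan
    bg[bg == 0] = np.nan
    return bg


def norm_ucount(counts5: np.ndarray, background: np.ndarray, position: int) -> float:
    """Protection value at a 1-based position; NaN if background is missing."""
    counts = np.asarray(counts5, dtype=float)
    if not 1 <= position <= counts.size:
        raise ScoringError(f"position {position} outside profile (1..{counts.size})")
    bg = background[position - 1]
    if np.isnan(bg):
        return float("nan")
    return float(counts[position - 1] / bg)


@dataclass(frozen=True)
class UProtectionTrack:
    """NormUcount and background vectors for one replicate profile."""

    molecule: str
    normu: np.ndarray
    background: np.ndarray
    replicate_id: str


def build_protection_track(
    profile: EndCountProfile, window: int = 10, exclude_self: bool = False
) -> UProtectionTrack:
    if profile.protocol != HYDRAPSI:
        raise ScoringError(
            f"protection tracks are defined for HydraPsi profiles, got "
            f"{profile.protocol!r}"
        )
    bg = rolling_background(profile.counts5, window=window, exclude_self=exclude_self)
    with np.errstate(invalid="ignore"):
        normu = profile.counts5 / bg
    return UProtectionTrack(
        molecule=profile.molecule,
        normu=normu,
        background=bg,
        replicate_id=profile.replicate_id,
    )


def u_profile(track: UProtectionTrack, ref: RnaReference) -> pd.Series:
    """NormUcount restricted to U residues; original coordinates are kept."""
    if ref.name != track.molecule:
        raise ScoringError(
            f"track is for {track.molecule!r}, reference is {ref.name!r}"
        )
    if ref.length != track.normu.size:
        raise ScoringError("track and reference lengths differ")
    u_positions = [p for p in range(1, ref.length + 1) if ref.residue(p) == "U"]
    return pd.Series(
        [track.normu[p - 1] for p in u_positions], index=u_positions, dtype=float
    )


def psiscore(uprof: pd.Series, position: int):
    """PsiScore = 1 - NormUcount at a U position; ``None`` when undefined."""
    if position not in uprof.index:
        raise ScoringError(f"position {position} is not a U position of this profile")
    val = uprof.loc[position]
    if np.isnan(val):
        return None
    return float(1.0 - val)


def scoremean(uprof: pd.Series, position: int, flank_u: int = 6):
    """Flanking-ratio score on the nearest defined U neighbours per side.

    Needs >= 3 defined U neighbours on each side; clipped above at 1, not
    floored below. ``None`` when the site value or the neighbourhood is
    unusable.
    """
    if position not in uprof.index:
        raise ScoringError(f"position {position} is not a U position of this profile")
    u_i = uprof.loc[position]
    if np.isnan(u_i):
        return None
    defined = uprof.dropna()
    left = defined[defined.index < position].iloc[-flank_u:]
    right = defined[defined.index > position].iloc[:flank_u]
    if len(left) < 3 or len(right) < 3:
        return None
    lbar, rbar = float(left.mean()), float(right.mean())
    if lbar + rbar == 0:
        return None
    return float(min(1.0 - 2.0 * float(u_i) / (lbar + rbar), 1.0))


def score_catalog_psi(
    profiles: Sequence[EndCountProfile],
    catalog: SiteCatalog,
    refs: Mapping[str, RnaReference],
    window: int = 10,
    exclude_self: bool = False,
    flank_u: int = 6,
) -> pd.DataFrame:
    """PsiScore (and scoremean) for every catalog site in every replicate."""
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
        ref = refs[molecule]
        for profile in by_molecule[molecule]:
            track = build_protection_track(
                profile, window=window, exclude_self=exclude_self
            )
            uprof = u_profile(track, ref)
            for site in catalog.subset(molecule=molecule):
                if site.mod_type != "Psi":
                    raise ScoringError(f"{site.label}: PsiScore applies to Psi sites")
                score = psiscore(uprof, site.position)
                if score is None:
                    warnings.warn(
                        f"{site.label} ({track.replicate_id}): PsiScore undefined "
                        "(missing local background)",
                        stacklevel=2,
                    )
                smean = scoremean(uprof, site.position, flank_u=flank_u)
                rows.append(
                    {
                        "molecule": site.molecule,
                        "position": site.position,
                        "residue": site.residue,
                        "mod_type": site.mod_type,
                        "replicate": track.replicate_id,
                        "score": np.nan if score is None else score,
                        "scoremean": np.nan if smean is None else smean,
                        "local_coverage": track.background[site.position - 1],
                    }
                )
    return pd.DataFrame(rows, columns=list(PSI_SCORE_COLUMNS))
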