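"""Estimator-validation utilities: recovery, bias, calibration, power.

These routines regenerate the package's headline numbers from scratch: they
simulate libraries at known ground truth, run the scorers, and report what
comes back. They are used both by the test suite and by the repository's
acceptance script, and are exported so users can re-validate the estimators
under their own parameter choices.
"""

from __future__ import annotations

import numpy as np

from .catalog import RnaReference
from .diff import paired_t
from .fixtures import (
    SHSY5Y_DIFF_NM_STOICHIOMETRY,
    demo_nm_catalog,
    demo_psi_catalog,
    demo_references,
    demo_truth_fractions,
    poly_u_reference,
)
from .hydrapsi import build_protection_track, psiscore, u_profile
from .pipeline import derive_seed
from .rms import build_cleavage_track, methscore, score_catalog_rms
from .simulate import HYDRAPSI, RMS, ProtocolParams, TruthProfile, simulate_hydrapsi, simulate_rms

__all__ = [
    "demo_methscore_recovery",
    "demo_psiscore_recovery",
    "cm2075_drop_percent",
    "catalog_counts",
    "methscore_bias_grid",
    "psiscore_bias_grid",
    "null_methscore_mean",
    "null_psiscore_mean",
    "type_i_error_rate",
    "power_rate",
]


def demo_methscore_recovery(
    molecule: str,
    position: int,
    condition: str,
    seed: int,
    depth: float = 20000.0,
    replicates: int = 3,
    flank: int = 6,
):
    """Simulate the demo Nm truth for one condition and recover a site's score.

    Returns ``(mean MethScore over replicates, true fraction)``.
    """
    refs = demo_references()
    catalog = demo_nm_catalog().subset(molecule=molecule)
    fractions = demo_truth_fractions(condition, "Nm")[molecule]
    truth = TruthProfile(molecule=molecule, fractions=fractions, mod_type="Nm")
    params = ProtocolParams(protocol=RMS, depth=depth, seed=seed)
    profiles = simulate_rms(refs[molecule], truth, params, replicates)
    table = score_catalog_rms(profiles, catalog, flank=flank)
    at_site = table[table["position"] == position]["score"].dropna()
    return float(at_site.mean()), fractions[position]


def demo_psiscore_recovery(
    molecule: str,
    position: int,
    condition: str,
    seed: int,
    depth: float = 5000.0,
    replicates: int = 3,
    window: int = 10,
):
    """Simulate the demo Psi truth for one condition and recover a PsiScore."""
    refs = demo_references()
    fractions = demo_truth_fractions(condition, "Psi")[molecule]
    truth = TruthProfile(molecule=molecule, fractions=fractions, mod_type="Psi")
    params = ProtocolParams(protocol=HYDRAPSI, depth=depth, seed=seed)
    profiles = simulate_hydrapsi(refs[molecule], truth, params, replicates)
    scores = []
    for profile in profiles:
        track = build_protection_track(profile, window=window, exclude_self=True)
        uprof = u_profile(track, refs[molecule])
        score = psiscore(uprof, position)
        if score is not None:
            scores.append(score)
    return float(np.mean(scores)), fractions[position]


def cm2075_drop_percent() -> float:
    """Percentage-point MethScore drop at 28S:2075, WT minus knockout.

    Exact arithmetic on the demo ground-truth stoichiometries of the
    differentiated-neuroblastoma contrast.
    """
    wt, ko = SHSY5Y_DIFF_NM_STOICHIOMETRY[("28S", 2075)]
    return round(100.0 * (wt - ko), 10)


def catalog_counts() -> dict[str, int]:
    """Per-molecule site counts of the packaged catalogs."""
    nm = demo_nm_catalog()
    psi = demo_psi_catalog()
    return {
        "nm_18S": nm.count(molecule="18S"),
        "nm_28S": nm.count(molecule="28S"),
        "nm_5.8S": nm.count(molecule="5.8S"),
        "psi_18S": psi.count(molecule="18S"),
        "psi_28S": psi.count(molecule="28S"),
        "psi_5.8S": psi.count(molecule="5.8S"),
    }


def _random_reference(rng, length: int = 60, name: str = "sim") -> RnaReference:
    return RnaReference(name, "".join(rng.choice(list("ACGU"), size=length)))


def methscore_bias_grid(
    fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
    depth: float = 2000.0,
    n_sims: int = 50,
    seed: int = 0,
    length: int = 60,
) -> dict[float, float]:
    """Mean recovered MethScore per true fraction (one interior site)."""
    position = length // 2
    rng = np.random.default_rng([seed, 1])
    ref = _random_reference(rng, length)
    out = {}
    for k, f in enumerate(fractions):
        truth = TruthProfile(ref.name, {position: f}, "Nm")
        scores = []
        for s in range(n_sims):
            params = ProtocolParams(
                protocol=RMS, depth=depth, seed=derive_seed(seed, k, s)
            )
            (profile,) = simulate_rms(ref, truth, params, 1)
            score = methscore(build_cleavage_track(profile), position)
            if score is not None:
                scores.append(score)
        out[f] = float(np.mean(scores))
    return out


def psiscore_bias_grid(
    fractions=(0.0, 0.3, 0.6, 0.9),
    depth: float = 2000.0,
    n_sims: int = 50,
    seed: int = 0,
    length: int = 60,
) -> dict[float, float]:
    """Mean recovered PsiScore per true fraction on an all-U substrate.

    Leave-one-out background keeps the queried position out of its own
    normalisation, isolating the protection signal.
    """
    position = length // 2
    ref = poly_u_reference(length)
    out = {}
    for k, f in enumerate(fractions):
        truth = TruthProfile(ref.name, {position: f}, "Psi")
        scores = []
        for s in range(n_sims):
            params = ProtocolParams(
                protocol=HYDRAPSI, depth=depth, seed=derive_seed(seed, 100 + k, s)
            )
            (profile,) = simulate_hydrapsi(ref, truth, params, 1)
            track = build_protection_track(profile, exclude_self=True)
            score = psiscore(u_profile(track, ref), position)
            if score is not None:
                scores.append(score)
        out[f] = float(np.mean(scores))
    return out


def null_methscore_mean(
    n_sims: int = 200, depth: float = 1000.0, seed: int = 0, length: int = 60
) -> float:
    """Mean MethScore at an interior site under zero methylation."""
    position = length // 2
    rng = np.random.default_rng([seed, 2])
    ref = _random_reference(rng, length)
    truth = TruthProfile(ref.name, {}, "Nm")
    scores = []
    for s in range(n_sims):
        params = ProtocolParams(protocol=RMS, depth=depth, seed=derive_seed(seed, 200, s))
        (profile,) = simulate_rms(ref, truth, params, 1)
        score = methscore(build_cleavage_track(profile), position)
        if score is not None:
            scores.append(score)
    return float(np.mean(scores))


def null_psiscore_mean(
    n_sims: int = 200, depth: float = 1000.0, seed: int = 0, length: int = 60
) -> float:
    """Mean PsiScore at an interior U under zero pseudouridylation."""
    position = length // 2
    ref = poly_u_reference(length)
    truth = TruthProfile(ref.name, {}, "Psi")
    scores = []
    for s in range(n_sims):
        params = ProtocolParams(
            protocol=HYDRAPSI, depth=depth, seed=derive_seed(seed, 300, s)
        )
        (profile,) = simulate_hydrapsi(ref, truth, params, 1)
        track = build_protection_track(profile)
        score = psiscore(u_profile(track, ref), position)
        if score is not None:
            scores.append(score)
    return float(np.mean(scores))


def _replicate_scores(ref, position, f, depth, n_reps, seed):
    truth = TruthProfile(ref.name, {position: f}, "Nm")
    params = ProtocolParams(protocol=RMS, depth=depth, seed=seed)
    profiles = simulate_rms(ref, truth, params, n_reps)
    return [
        methscore(build_cleavage_track(p), position) for p in profiles
    ]


def type_i_error_rate(
    n_sims: int = 1000,
    depth: float = 1000.0,
    truth_f: float = 0.5,
    n_reps: int = 3,
    seed: int = 0,
    length: int = 30,
) -> float:
    """Fraction of null (equal-truth) site simulations with p <= 0.05."""
    position = length // 2
    rng = np.random.default_rng([seed, 3])
    ref = _random_reference(rng, length)
    hits = 0
    for s in range(n_sims):
        a = _replicate_scores(ref, position, truth_f, depth, n_reps, derive_seed(seed, 400, s, 0))
        b = _replicate_scores(ref, position, truth_f, depth, n_reps, derive_seed(seed, 400, s, 1))
        result = paired_t(a, b)
        if result.p <= 0.05:
            hits += 1
    return hits / n_sims


def power_rate(
    f_ref: float = 0.3,
    f_alt: float = 0.6,
    n_sims: int = 200,
    depth: float = 2000.0,
    n_reps: int = 3,
    seed: int = 0,
    length: int = 30,
) -> float:
    """Fraction of simulations detecting a true stoichiometry shift (p <= 0.05)."""
    position = length // 2
    rng = np.random.default_rng([seed, 4])
    ref = _random_reference(rng, length)
    hits = 0
    for s in range(n_sims):
        a = _replicate_scores(ref, position, f_ref, depth, n_reps, derive_seed(seed, 500, s, 0))
        b = _replicate_scores(ref, position, f_alt, depth, n_reps, derive_seed(seed, 500, s, 1))
        result = paired_t(a, b)
        if result.p <= 0.05:
            hits += 1
    return hits / n_sims
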