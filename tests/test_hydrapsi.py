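import numpy as np
import pandas as pd
import pytest

from ribomod import (
    ProtocolParams,
    RnaReference,
    ScoringError,
    TruthProfile,
    build_protection_track,
    norm_ucount,
    psiscore,
    rolling_background,
    score_catalog_psi,
    scoremean,
    simulate_hydrapsi,
    u_profile,
)
from ribomod.benchmarks import null_psiscore_mean, psiscore_bias_grid
from ribomod.fixtures import poly_u_reference
from ribomod.simulate import HYDRAPSI


class TestRollingBackground:
    def test_constant_counts_give_constant_interior_background(self):
        bg = rolling_background(np.full(30, 7.0))
        assert np.allclose(bg[10:20], 7.0)

    def test_zero_coverage_gives_missing_background(self):
        assert np.isnan(rolling_background(np.zeros(30))).all()

    def test_hand_mean_around_a_dropout(self):
        counts = np.array([10, 10, 10, 10, 10, 0, 10, 10, 10, 10], dtype=float)
        bg = rolling_background(counts, window=10)
        assert bg[5] == pytest.approx(9.0)  # full 10-wide window around the 0

    def test_window_below_two_rejected(self):
        with pytest.raises(ScoringError, match="window"):
            rolling_background(np.ones(10), window=1)

    def test_centering_convention_invisible_on_constant_input(self):
        counts = np.full(40, 5.0)
        even = rolling_background(counts, window=10)
        odd = rolling_background(counts, window=11)
        interior = slice(10, 30)
        assert np.allclose(even[interior], odd[interior])

    def test_leave_one_out_excludes_the_queried_position(self):
        counts = np.full(30, 10.0)
        counts[15] = 0.0
        plain = rolling_background(counts)
        loo = rolling_background(counts, exclude_self=True)
        assert plain[15] == pytest.approx(9.0)
        assert loo[15] == pytest.approx(10.0)


class TestNormUcountAndPsiScore:
    def test_background_level_cleavage_scores_zero(self):
        counts = np.full(30, 7.0)
        bg = rolling_background(counts)
        assert norm_ucount(counts, bg, 15) == pytest.approx(1.0)
        uprof = pd.Series({15: 1.0})
        assert psiscore(uprof, 15) == pytest.approx(0.0)

    def test_full_protection_scores_one(self):
        uprof = pd.Series({15: 0.0})
        assert psiscore(uprof, 15) == pytest.approx(1.0)

    def test_hyper_reactive_residue_scores_negative(self):
        # cleavage at 4.9x the local background: score 1 - 4.9 = -3.9
        uprof = pd.Series({15: 4.9})
        assert psiscore(uprof, 15) == pytest.approx(-3.9)

    def test_missing_background_propagates_to_missing_score(self):
        counts = np.zeros(30)
        bg = rolling_background(counts)
        assert np.isnan(norm_ucount(counts, bg, 15))
        assert psiscore(pd.Series({15: np.nan}), 15) is None

    def test_score_bounded_above_by_one(self):
        rng = np.random.default_rng(1)
        uprof = pd.Series(rng.uniform(0, 5, size=20), index=range(1, 21))
        scores = [psiscore(uprof, p) for p in uprof.index]
        assert all(s <= 1.0 for s in scores)


class TestUProfile:
    def test_keeps_exactly_the_u_positions(self):
        ref = RnaReference("x", "AUGUCCUAAG")
        counts = np.arange(1, 11, dtype=np.int64)
        from ribomod.simulate import EndCountProfile

        profile = EndCountProfile("x", counts, np.zeros(10, dtype=np.int64), "r", HYDRAPSI)
        track = build_protection_track(profile, window=4)
        uprof = u_profile(track, ref)
        assert list(uprof.index) == [2, 4, 7]  # original coordinates, no re-indexing

    def test_no_uridines_gives_empty_profile(self):
        ref = RnaReference("g", "G" * 12)
        from ribomod.simulate import EndCountProfile

        profile = EndCountProfile(
            "g", np.ones(12, dtype=np.int64), np.zeros(12, dtype=np.int64), "r", HYDRAPSI
        )
        uprof = u_profile(build_protection_track(profile), ref)
        assert len(uprof) == 0


class TestScoreMean:
    def _uprof(self, values):
        return pd.Series(values, index=range(1, len(values) + 1), dtype=float)

    def test_constant_profile_scores_zero(self):
        assert scoremean(self._uprof([1.0] * 15), 8) == pytest.approx(0.0)

    def test_protected_site_scores_one(self):
        values = [1.0] * 15
        values[7] = 0.0
        assert scoremean(self._uprof(values), 8) == pytest.approx(1.0)

    def test_hand_value(self):
        values = [1.0] * 15
        values[7] = 0.4
        assert scoremean(self._uprof(values), 8) == pytest.approx(0.6)

    def test_insufficient_u_neighbours_is_missing(self):
        assert scoremean(self._uprof([1.0] * 15), 2) is None


class TestScoreCatalogPsi:
    def test_cardinality_and_two_replicate_minimum(self, refs, psi_catalog):
        catalog = psi_catalog.subset(molecule="5.8S")
        fractions = {s.position: 0.5 for s in catalog}
        truth = TruthProfile("5.8S", fractions, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=1000, seed=3)
        profiles = simulate_hydrapsi(refs["5.8S"], truth, params, 2)
        table = score_catalog_psi(profiles, catalog, refs)
        assert len(table) == len(catalog) * 2
        assert table["score"].notna().all()
        assert "scoremean" in table.columns

    def test_scale_invariance_of_scores(self, refs, psi_catalog):
        catalog = psi_catalog.subset(molecule="5.8S")
        truth = TruthProfile("5.8S", {s.position: 0.4 for s in catalog}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=1000, seed=5)
        (profile,) = simulate_hydrapsi(refs["5.8S"], truth, params, 1)
        from ribomod.simulate import EndCountProfile

        scaled = EndCountProfile(
            profile.molecule,
            profile.counts5 * 7,
            profile.counts3,
            profile.replicate_id,
            profile.protocol,
        )
        a = score_catalog_psi([profile], catalog, refs)
        b = score_catalog_psi([scaled], catalog, refs)
        assert np.allclose(a["score"], b["score"])

    def test_rms_profile_rejected(self, refs, psi_catalog):
        from ribomod.simulate import RMS, EndCountProfile

        profile = EndCountProfile(
            "5.8S",
            np.ones(157, dtype=np.int64),
            np.ones(157, dtype=np.int64),
            "r",
            RMS,
        )
        with pytest.raises(ScoringError, match="HydraPsi"):
            score_catalog_psi([profile], psi_catalog.subset(molecule="5.8S"), refs)


class TestEstimatorProperties:
    def test_recovery_bias_below_four_points(self):
        grid = psiscore_bias_grid(depth=2000.0, n_sims=50, seed=0)
        for f, mean in grid.items():
            assert abs(mean - f) < 0.04, f"bias at f={f}: {mean}"

    def test_null_mean_within_three_points(self):
        assert abs(null_psiscore_mean(n_sims=200, depth=1000.0, seed=0)) < 0.03

    def test_negative_scores_iff_cleavage_above_background(self):
        # an unprotected U in a U-rich context sits near 0; doubling its
        # cleavage pushes the score strictly negative
        ref = poly_u_reference(40)
        truth = TruthProfile(ref.name, {}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=2000, seed=8)
        (profile,) = simulate_hydrapsi(ref, truth, params, 1)
        boosted = profile.counts5.copy()
        boosted[19] *= 3
        from ribomod.simulate import EndCountProfile

        hyper = EndCountProfile(ref.name, boosted, profile.counts3, "r", HYDRAPSI)
        track = build_protection_track(hyper, exclude_self=True)
        assert psiscore(u_profile(track, ref), 20) < 0
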