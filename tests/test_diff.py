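import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribomod import (
    ProtocolParams,
    ScoreMatrix,
    TruthProfile,
    diff_table,
    heatmap_matrix,
    paired_t,
    score_catalog_rms,
    simulate_rms,
)
from ribomod.benchmarks import power_rate, type_i_error_rate
from ribomod.diff import DiffError, stars_for_p
from ribomod.simulate import RMS


class TestPairedT:
    @pytest.mark.parametrize(
        "ref,alt",
        [
            ((0.60, 0.62, 0.58), (0.70, 0.74, 0.69)),
            ((0.1, 0.5, 0.3, 0.2), (0.15, 0.4, 0.45, 0.3)),
            ((0.9, 0.8), (0.7, 0.75)),
        ],
    )
    def test_matches_independent_oracle(self, ref, alt):
        mine = paired_t(ref, alt)
        oracle = stats.ttest_rel(alt, ref)
        assert mine.t == pytest.approx(oracle.statistic)
        assert mine.p == pytest.approx(oracle.pvalue)
        assert mine.df == len(ref) - 1

    def test_identical_vectors_give_p_one(self):
        result = paired_t((0.3, 0.3, 0.3), (0.3, 0.3, 0.3))
        assert result.p == 1.0 and result.t == 0.0 and not result.degenerate

    def test_constant_nonzero_shift_is_flagged_degenerate(self):
        result = paired_t((0.1, 0.2, 0.3), (0.2, 0.3, 0.4))
        assert result.degenerate and result.p == 0.0 and np.isinf(result.t)

    def test_length_mismatch_and_tiny_n_rejected(self):
        with pytest.raises(DiffError):
            paired_t((0.1, 0.2), (0.1,))
        with pytest.raises(DiffError):
            paired_t((0.1,), (0.2,))


def _matrix(site_scores):
    """site_scores: {(mol, pos, mod): {cond: [scores]}} -> ScoreMatrix."""
    rows = []
    conditions: list[str] = []
    for (mol, pos, mod), by_cond in site_scores.items():
        for cond, scores in by_cond.items():
            if cond not in conditions:
                conditions.append(cond)
            for i, s in enumerate(scores, start=1):
                rows.append(
                    dict(molecule=mol, position=pos, mod_type=mod,
                         condition=cond, replicate=f"rep{i}", score=s)
                )
    return ScoreMatrix(pd.DataFrame(rows), tuple(conditions))


class TestDiffTable:
    def test_thresholds_affected_strict_heatmap_inclusive(self):
        matrix = _matrix(
            {
                ("18S", 100, "Nm"): {"WT": [0.50, 0.52, 0.48], "KO": [0.57, 0.58, 0.55]},
                ("18S", 200, "Nm"): {"WT": [0.50, 0.52, 0.48], "KO": [0.60, 0.62, 0.58]},
                ("18S", 300, "Nm"): {"WT": [0.50, 0.52, 0.48], "KO": [0.51, 0.53, 0.49]},
            }
        )
        table = diff_table(matrix, "WT", "KO").set_index("position")
        # delta 0.0667: affected (>0.05) but not heatmap (<0.1)
        assert bool(table.loc[100, "affected"]) and not bool(table.loc[100, "heatmap"])
        # delta 0.1: both (heatmap is inclusive)
        assert bool(table.loc[200, "affected"]) and bool(table.loc[200, "heatmap"])
        assert table.loc[200, "direction"] == "up"
        # delta 0.01: neither, direction none
        assert not bool(table.loc[300, "affected"])
        assert table.loc[300, "direction"] == "none"

    def test_swapping_conditions_negates_delta_keeps_p(self):
        matrix = _matrix(
            {("18S", 100, "Nm"): {"WT": [0.3, 0.35, 0.32], "KO": [0.5, 0.52, 0.56]}}
        )
        fwd = diff_table(matrix, "WT", "KO").iloc[0]
        rev = diff_table(matrix, "KO", "WT").iloc[0]
        assert fwd["delta"] == pytest.approx(-rev["delta"])
        assert fwd["p_raw"] == pytest.approx(rev["p_raw"])
        assert (fwd["direction"], rev["direction"]) == ("up", "down")

    def test_site_with_fewer_than_two_pairs_skipped_with_warning(self):
        matrix = _matrix(
            {("18S", 100, "Nm"): {"WT": [0.3, np.nan, np.nan], "KO": [0.5, 0.52, 0.56]}}
        )
        with pytest.warns(UserWarning, match="pair"):
            table = diff_table(matrix, "WT", "KO")
        assert len(table) == 0

    def test_unknown_condition_rejected(self):
        matrix = _matrix({("18S", 100, "Nm"): {"WT": [0.3, 0.4], "KO": [0.5, 0.6]}})
        with pytest.raises(DiffError, match="MUT"):
            diff_table(matrix, "WT", "MUT")

    def test_simulated_fus_ko_contrast_is_called_up(self, small_ref, small_nm_catalog):
        tables = {}
        for cond, f, seed in (("WT", 0.02, 10), ("KO", 0.31, 20)):
            truth = TruthProfile("mini", {20: f}, "Nm")
            params = ProtocolParams(protocol=RMS, depth=2000, seed=seed)
            profiles = simulate_rms(small_ref, truth, params, 3)
            tables[cond] = score_catalog_rms(profiles, small_nm_catalog)
        table = diff_table(ScoreMatrix.from_tables(tables), "WT", "KO").iloc[0]
        assert table["direction"] == "up"
        assert bool(table["affected"]) and bool(table["heatmap"])

    def test_equal_truths_rarely_called_affected(self, small_ref, small_nm_catalog):
        from ribomod.pipeline import derive_seed

        hits = 0
        for s in range(100):
            tables = {}
            for k, cond in enumerate(("WT", "KO")):
                truth = TruthProfile("mini", {20: 0.5}, "Nm")
                params = ProtocolParams(
                    protocol=RMS, depth=2000, seed=derive_seed(0, s, k)
                )
                profiles = simulate_rms(small_ref, truth, params, 3)
                tables[cond] = score_catalog_rms(profiles, small_nm_catalog)
            row = diff_table(ScoreMatrix.from_tables(tables), "WT", "KO").iloc[0]
            hits += int(row["affected"])
        assert hits <= 5  # null |delta| > 0.05 in at most 5% of simulations

    def test_stars_monotone_in_p(self):
        ps = [0.0005, 0.001, 0.005, 0.01, 0.03, 0.05, 0.2, np.nan]
        assert [stars_for_p(p) for p in ps] == [
            "***", "***", "**", "**", "*", "*", "ns", "ns",
        ]


class TestHeatmapMatrix:
    def _diff(self, rows):
        return pd.DataFrame(
            rows,
            columns=["molecule", "position", "mod_type", "delta", "heatmap"],
        )

    def test_empty_result_is_a_valid_frame(self):
        table = self._diff([("18S", 100, "Nm", 0.05, False)])
        hm = heatmap_matrix([("KO_vs_WT", table)])
        assert len(hm) == 0
        assert list(hm.columns) == ["molecule", "position", "mod_type", "KO_vs_WT"]

    def test_single_eligible_site_single_row(self):
        table = self._diff(
            [("18S", 354, "Nm", 0.29, True), ("18S", 100, "Nm", 0.02, False)]
        )
        hm = heatmap_matrix([("KO_vs_WT", table)])
        assert len(hm) == 1
        assert hm.iloc[0]["position"] == 354
        assert hm.iloc[0]["KO_vs_WT"] == pytest.approx(0.29)

    def test_column_order_follows_comparison_order(self):
        a = self._diff([("18S", 354, "Nm", 0.29, True)])
        b = self._diff([("18S", 354, "Nm", 0.12, True)])
        hm = heatmap_matrix([("second", b), ("first", a)])
        assert list(hm.columns)[-2:] == ["second", "first"]


class TestCalibration:
    def test_type_i_error_near_nominal(self):
        rate = type_i_error_rate(n_sims=1000, depth=1000.0, seed=0)
        # 0.05 +/- 3 binomial SE at n = 1000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_power_for_a_point_three_shift(self):
        assert power_rate(n_sims=200, depth=2000.0, seed=0) > 0.9
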