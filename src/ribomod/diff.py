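"""Differential modification calling between conditions.

Replicate-level scores are aggregated per condition and each site is tested
with a paired Student's t-test on within-pair (same replicate label across
conditions) differences. Classification follows two distinct thresholds:

* ``affected``          — |delta| strictly greater than 0.05,
* ``heatmap_eligible``  — |delta| >= 0.1 (the export rule for heatmaps),

with significance stars on the raw two-sided p (* <= 0.05, ** <= 0.01,
*** <= 0.001). No multiple-testing correction drives the calls; a
Benjamini-Hochberg column is emitted alongside for reference only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiffError",
    "TTestResult",
    "paired_t",
    "ScoreMatrix",
    "diff_table",
    "heatmap_matrix",
    "stars_for_p",
    "AFFECTED_THRESHOLD",
    "HEATMAP_THRESHOLD",
]

AFFECTED_THRESHOLD = 0.05  # strictly greater
HEATMAP_THRESHOLD = 0.1  # greater or equal

DIFF_COLUMNS = (
    "molecule",
    "position",
    "mod_type",
    "n_pairs",
    "mean_ref",
    "mean_alt",
    "delta",
    "t",
    "p_raw",
    "p_bh",
    "stars",
    "affected",
    "heatmap",
    "direction",
    "degenerate",
)


class DiffError(ValueError):
    pass


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t(scores_ref: Sequence[float], scores_alt: Sequence[float]) -> TTestResult:
    """Paired Student's t-test from the closed form of the statistic.

    t = mean(d) / (sd(d) / sqrt(n)) on within-pair differences d = alt - ref,
    df = n - 1, two-sided p from the t distribution. Degenerate inputs follow
    two conventions: all differences identically zero -> p = 1; zero variance
    with a non-zero mean difference -> p reported as the 0 limit and flagged.
    """
    ref = np.asarray(scores_ref, dtype=float)
    alt = np.asarray(scores_alt, dtype=float)
    if ref.shape != alt.shape or ref.ndim != 1:
        raise DiffError("paired t-test needs two equal-length score vectors")
    n = ref.size
    if n < 2:
        raise DiffError("paired t-test needs at least 2 pairs")
    d = alt - ref
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d < 1e-12:  # identical differences up to float rounding
        if abs(mean_d) < 1e-12:
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=False)
        t = math.copysign(math.inf, mean_d)
        return TTestResult(t=t, p=0.0, df=df, degenerate=True)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, df=df, degenerate=False)


def stars_for_p(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ScoreMatrix:
    """Long-format site x condition x replicate score values.

    ``data`` columns: molecule, position, mod_type, condition, replicate,
    score. The first entry of ``conditions`` is the reference condition.
    """

    data: pd.DataFrame
    conditions: tuple[str, ...]

    REQUIRED = ("molecule", "position", "mod_type", "condition", "replicate", "score")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise DiffError(f"score matrix missing columns {sorted(missing)}")
        unknown = set(self.data["condition"]) - set(self.conditions)
        if unknown:
            raise DiffError(f"conditions {sorted(unknown)} not declared")

    @classmethod
    def from_tables(cls, tables: Mapping[str, pd.DataFrame]) -> "ScoreMatrix":
        """Assemble from per-condition score tables (condition -> ScoreTable)."""
        frames = []
        for condition, table in tables.items():
            frame = table.copy()
            frame["condition"] = condition
            frames.append(frame[list(cls.REQUIRED)])
        return cls(pd.concat(frames, ignore_index=True), tuple(tables))


def diff_table(
    matrix: ScoreMatrix,
    ref_condition: str,
    alt_condition: str,
    affected_threshold: float = AFFECTED_THRESHOLD,
    heatmap_threshold: float = HEATMAP_THRESHOLD,
) -> pd.DataFrame:
    """Per-site condition comparison with paired testing and classification.

    Sites with fewer than 2 complete replicate pairs are skipped with a
    warning; exactly 2 pairs runs the test at df = 1 (low power, but the
    minimum the design admits).
    """
    for cond in (ref_condition, alt_condition):
        if cond not in matrix.conditions:
            raise DiffError(f"condition {cond!r} not present in score matrix")
    data = matrix.data
    rows = []
    site_keys = (
        data[["molecule", "position", "mod_type"]]
        .drop_duplicates()
        .sort_values(["molecule", "position", "mod_type"])
    )
    for _, key in site_keys.iterrows():
        mask = (
            (data["molecule"] == key["molecule"])
            & (data["position"] == key["position"])
            & (data["mod_type"] == key["mod_type"])
        )
        sub = data[mask]
        ref = sub[sub["condition"] == ref_condition].set_index("replicate")["score"]
        alt = sub[sub["condition"] == alt_condition].set_index("replicate")["score"]
        paired = pd.DataFrame({"ref": ref, "alt": alt}).dropna()
        if len(paired) < 2:
            warnings.warn(
                f"{key['molecule']}:{key['position']} ({key['mod_type']}): "
                f"only {len(paired)} complete replicate pair(s); site skipped",
                stacklevel=2,
            )
            continue
        result = paired_t(paired["ref"].to_numpy(), paired["alt"].to_numpy())
        mean_ref = float(ref.dropna().mean())
        mean_alt = float(alt.dropna().mean())
        delta = mean_alt - mean_ref
        # round away float noise so the threshold comparisons behave like
        # exact arithmetic at the published boundaries (0.05 strict, 0.1 incl.)
        abs_delta = round(abs(delta), 9)
        affected = abs_delta > affected_threshold
        direction = "none"
        if affected:
            direction = "up" if delta > 0 else "down"
        rows.append(
            {
                "molecule": key["molecule"],
                "position": key["position"],
                "mod_type": key["mod_type"],
                "n_pairs": len(paired),
                "mean_ref": mean_ref,
                "mean_alt": mean_alt,
                "delta": delta,
                "t": result.t,
                "p_raw": result.p,
                "p_bh": np.nan,
                "stars": stars_for_p(result.p),
                "affected": affected,
                "heatmap": abs_delta >= heatmap_threshold,
                "direction": direction,
                "degenerate": result.degenerate,
            }
        )
    table = pd.DataFrame(rows, columns=list(DIFF_COLUMNS))
    if len(table):
        table["p_bh"] = stats.false_discovery_control(table["p_raw"].clip(0, 1))
    return table


def heatmap_matrix(comparisons: Sequence[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Site x comparison delta matrix over heatmap-eligible sites.

    Rows are sites heatmap-eligible in at least one comparison; columns
    follow the comparison order given. An empty (0-row) frame with the right
    columns is a valid result.
    """
    if not comparisons:
        raise DiffError("at least one comparison is required")
    labels = [label for label, _ in comparisons]
    if len(set(labels)) != len(labels):
        raise DiffError("comparison labels must be unique")
    eligible: dict[tuple, dict[str, float]] = {}
    order: list[tuple] = []
    for label, table in comparisons:
        for _, row in table.iterrows():
            key = (row["molecule"], row["position"], row["mod_type"])
            if key not in eligible:
                eligible[key] = {}
                order.append(key)
            eligible[key][label] = row["delta"]
    keep = [
        key
        for key in sorted(order)
        if any(
            bool(
                table.loc[
                    (table["molecule"] == key[0])
                    & (table["position"] == key[1])
                    & (table["mod_type"] == key[2]),
                    "heatmap",
                ].any()
            )
            for _, table in comparisons
        )
    ]
    records = []
    for key in keep:
        rec = {"molecule": key[0], "position": key[1], "mod_type": key[2]}
        for label in labels:
            rec[label] = eligible[key].get(label, np.nan)
        records.append(rec)
    return pd.DataFrame(records, columns=["molecule", "position", "mod_type"] + labels)
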