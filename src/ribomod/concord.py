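"""snoRNA guide-target concordance.

Site-specific 2'-O-methylation is guided by C/D-box snoRNAs and
pseudouridylation by H/ACA-box snoRNAs, so a change in a site's modification
stoichiometry may be explained directly by a change in the abundance of its
guide(s). This module joins per-site differential calls with an externally
computed snoRNA differential-expression table (DESeq2-style export and/or
RT-qPCR summaries) and classifies each site:

* ``concordant``     — at least one guide changes significantly in the same
                       direction as the site and none significantly opposes;
* ``discordant``     — the site changed but every significant guide (if any)
                       opposes it; a changed site with no significant guide
                       change also lands here (unsupported by guides);
* ``partial``        — significant guides disagree with each other;
* ``no_guide``       — the site has no annotated guide (orphan);
* ``site_unchanged`` — the site itself did not move.

When both small-RNA-seq and qPCR evidence exist for one guide, any
significant source suffices by default; ``strict=True`` requires every
source reporting the guide to be significant and to agree in sign. A guide
whose sources significantly conflict is treated as giving no direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import SiteCatalog

__all__ = [
    "ConcordError",
    "GuideCall",
    "ConcordanceCall",
    "read_de_table",
    "classify_concordance",
    "concord_table",
    "concordance_summary",
    "VERDICTS",
]

VERDICTS = ("concordant", "discordant", "partial", "no_guide", "site_unchanged")

DE_COLUMNS = ("snorna", "log2fc", "padj", "source")


class ConcordError(ValueError):
    pass


@dataclass(frozen=True)
class GuideCall:
    guide: str
    direction: str  # "up" | "down" | "none"
    significant: bool


@dataclass(frozen=True)
class ConcordanceCall:
    molecule: str
    position: int
    mod_type: str
    site_direction: str
    guide_calls: tuple[GuideCall, ...]
    verdict: str


def read_de_table(path) -> pd.DataFrame:
    """Read a guide differential-expression TSV (snorna, log2fc, padj, source)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(DE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ConcordError(f"{path}: missing DE columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "smallRNAseq"
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ConcordError(f"{path}: padj outside [0, 1]")
    dup = df.duplicated(subset=["snorna", "source"])
    if dup.any():
        raise ConcordError(
            f"{path}: duplicate (snorna, source) rows: "
            f"{sorted(df.loc[dup, 'snorna'].unique())}"
        )
    return df


def _guide_direction(
    guide: str,
    de: pd.DataFrame,
    fc_threshold: float,
    sig_threshold: float,
    strict: bool,
) -> GuideCall:
    rows = de[de["snorna"] == guide]
    if rows.empty:
        return GuideCall(guide, "none", False)
    sig = rows[(rows["padj"] <= sig_threshold) & (rows["log2fc"].abs() > fc_threshold)]
    signs = {1 if fc > 0 else -1 for fc in sig["log2fc"]}
    if strict:
        # every source reporting the guide must be significant and agree
        if len(sig) != len(rows) or len(signs) != 1:
            return GuideCall(guide, "none", False)
    if len(signs) == 1:
        return GuideCall(guide, "up" if signs == {1} else "down", True)
    # empty (not significant) or conflicting sources
    return GuideCall(guide, "none", False)


def classify_concordance(
    molecule: str,
    position: int,
    mod_type: str,
    site_direction: str,
    guides: Sequence[str],
    de: pd.DataFrame,
    fc_threshold: float = 0.0,
    sig_threshold: float = 0.05,
    strict: bool = False,
) -> ConcordanceCall:
    """Classify one site's direction against its guides' expression changes."""
    calls = tuple(
        _guide_direction(g, de, fc_threshold, sig_threshold, strict) for g in guides
    )
    if not guides:
        verdict = "no_guide"
    elif site_direction == "none":
        verdict = "site_unchanged"
    else:
        same = any(c.significant and c.direction == site_direction for c in calls)
        opposite = any(
            c.significant and c.direction not in (site_direction, "none")
            for c in calls
        )
        if same and not opposite:
            verdict = "concordant"
        elif same and opposite:
            verdict = "partial"
        else:
            verdict = "discordant"
    return ConcordanceCall(
        molecule=molecule,
        position=position,
        mod_type=mod_type,
        site_direction=site_direction,
        guide_calls=calls,
        verdict=verdict,
    )


def concord_table(
    diff: pd.DataFrame,
    catalog: SiteCatalog,
    de: pd.DataFrame,
    fc_threshold: float = 0.0,
    sig_threshold: float = 0.05,
    strict: bool = False,
) -> tuple[list[ConcordanceCall], pd.DataFrame]:
    """Classify every site of a differential table; returns (calls, report)."""
    calls = []
    for _, row in diff.iterrows():
        site = catalog.get(row["molecule"], int(row["position"]), row["mod_type"])
        calls.append(
            classify_concordance(
                site.molecule,
                site.position,
                site.mod_type,
                row["direction"],
                site.guides,
                de,
                fc_threshold=fc_threshold,
                sig_threshold=sig_threshold,
                strict=strict,
            )
        )
    records = []
    for call in calls:
        records.append(
            {
                "molecule": call.molecule,
                "position": call.position,
                "mod_type": call.mod_type,
                "site_direction": call.site_direction,
                "guides": ";".join(c.guide for c in call.guide_calls) or "Unknown",
                "guide_directions": ";".join(
                    f"{c.guide}:{c.direction}{'*' if c.significant else ''}"
                    for c in call.guide_calls
                ),
                "verdict": call.verdict,
            }
        )
    report = pd.DataFrame(
        records,
        columns=[
            "molecule",
            "position",
            "mod_type",
            "site_direction",
            "guides",
            "guide_directions",
            "verdict",
        ],
    ).sort_values(["molecule", "position", "mod_type"], ignore_index=True)
    return calls, report


def concordance_summary(calls: Iterable[ConcordanceCall]) -> dict[str, int]:
    """Deterministic verdict counts (always all five verdicts, fixed order)."""
    summary = {v: 0 for v in VERDICTS}
    for call in calls:
        summary[call.verdict] += 1
    return summary
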