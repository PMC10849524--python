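"""Differential-methylation / differential-expression filtering and the
inverse-association join.

Filters mirror the upstream pipelines' screening rules: differentially
methylated regions keep |percent methylation difference| > 5 at q < 0.05
(magnitude boundary exclusive); differentially expressed genes keep
|log2FC| >= 0.263 (a 20% fold change, boundary inclusive) at adjusted
p < 0.05.  The join classifies promoter methylation changes that run
opposite to expression: hypomethylated/up-regulated and
hypermethylated/down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DM_COLUMNS = ["gene", "region", "meth_diff", "q"]
DEG_COLUMNS = ["gene", "log2fc", "padj"]


@dataclass(frozen=True)
class IntegrationThresholds:
    meth_diff_min: float = 5.0  # pp, absolute, exclusive
    q_max: float = 0.05
    padj_max: float = 0.05
    log2fc_min: float = 0.263  # |log2(1.2)| to 3 dp, inclusive
    min_coverage: int = 10

    def __post_init__(self) -> None:
        if min(self.meth_diff_min, self.q_max, self.padj_max, self.log2fc_min) <= 0:
            raise ValueError("all thresholds must be positive")


def _require(df: pd.DataFrame, cols: list[str], kind: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing columns {sorted(missing)}")


def filter_dm(
    records: pd.DataFrame, thresholds: IntegrationThresholds = IntegrationThresholds()
) -> pd.DataFrame:
    """Keep regions with |meth_diff| > threshold and q below the cutoff.

    Honors a minimum-coverage filter when a ``coverage`` column is present.
    Adds a ``direction`` column (hypo for negative differences, hyper for
    positive).
    """
    _require(records, DM_COLUMNS, "differential-methylation")
    df = records.copy()
    if (df["meth_diff"].abs() > 100).any():
        raise ValueError("meth_diff outside [-100, 100]")
    if "coverage" in df.columns:
        df = df[df["coverage"] >= thresholds.min_coverage]
    kept = df[
        (df["meth_diff"].abs() > thresholds.meth_diff_min) & (df["q"] < thresholds.q_max)
    ].copy()
    kept["direction"] = np.where(kept["meth_diff"] < 0, "hypo", "hyper")
    return kept.reset_index(drop=True)


def filter_deg(
    records: pd.DataFrame, thresholds: IntegrationThresholds = IntegrationThresholds()
) -> pd.DataFrame:
    """Keep genes with padj below cutoff and |log2FC| at or above cutoff."""
    _require(records, DEG_COLUMNS, "differential-expression")
    df = records.copy()
    kept = df[
        (df["padj"] < thresholds.padj_max) & (df["log2fc"].abs() >= thresholds.log2fc_min)
    ].copy()
    kept["fold_change"] = 2.0 ** kept["log2fc"]
    return kept.reset_index(drop=True)


def integrate(dm: pd.DataFrame, deg: pd.DataFrame) -> pd.DataFrame:
    """Join filtered methylation and expression tables and classify.

    hypo-up: promoter hypomethylation with increased expression;
    hyper-down: hypermethylation with decreased expression; everything else
    concordant.  Output sorted by |meth_diff| descending.
    """
    for df, kind in ((dm, "methylation"), (deg, "expression")):
        dup = df["gene"][df["gene"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate gene rows in {kind} table: {sorted(set(dup))}")
    joined = dm.merge(deg, on="gene", how="inner")
    if "fold_change" not in joined.columns:
        joined["fold_change"] = 2.0 ** joined["log2fc"]
    conditions = [
        (joined["meth_diff"] < 0) & (joined["fold_change"] > 1),
        (joined["meth_diff"] > 0) & (joined["fold_change"] < 1),
    ]
    joined["association"] = np.select(conditions, ["hypo-up", "hyper-down"], "concordant")
    return (
        joined.assign(_absmd=joined["meth_diff"].abs())
        .sort_values("_absmd", ascending=False, kind="stable")
        .drop(columns="_absmd")
        .reset_index(drop=True)
    )
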