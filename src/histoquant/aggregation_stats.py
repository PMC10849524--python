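"""Abundance normalization, aggregate PTM metrics, comparisons, statistics.

Proteoform abundances are expressed as percent of the histone family per
sample (absolute stoichiometry), technical replicates averaged after
normalization.  Aggregates follow the field's bracket semantics: a ``{}``
(discrete-PTM) value is the summed abundance of every proteoform carrying
the marks; bulk metrics count side-chain acetyls (H4's fixed N-terminal
acetyl excluded) and methyl groups with me1/me2/me3 = 1/2/3.

Comparisons report both the percentage-point difference of group means —
read as the fraction of the genome affected — and the fold change of group
means, with Welch's t (2 groups) or one-way ANOVA + Tukey (3 groups).
Multiple testing: classic Benjamini-Hochberg and the two-stage linear
step-up of Benjamini, Krieger & Yekutieli, both implemented here and
cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteoform_space import (
    ContainsQuery,
    ExactQuery,
    Proteoform,
    Query,
    SiteStateSchema,
    parse_notation,
    realize_exact,
)

ABUNDANCE_SUM_TOL = 1e-6


@dataclass(frozen=True)
class StatThresholds:
    alpha: float = 0.05
    fold_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_cutoff <= 1:
            raise ValueError("fold cutoff must exceed 1")


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    pp_change: float  # mean_a - mean_b, percentage points
    fold_change: float  # mean_a / mean_b
    p: float | None
    significant: bool | None  # p < alpha AND fold >= cutoff (or <= 1/cutoff)


@dataclass
class ComparisonResult:
    metric: str
    group_means: dict[str, float]
    pairwise: list[PairwiseComparison]
    anova_p: float | None = None  # only for 3 groups

    @property
    def pp_change(self) -> float:
        return self.pairwise[0].pp_change

    @property
    def fold_change(self) -> float:
        return self.pairwise[0].fold_change

    @property
    def p(self) -> float | None:
        return self.pairwise[0].p


# ---------------------------------------------------------------------------
# Normalization


def normalize(
    class_quants: Mapping[tuple[str, int], Sequence[tuple[float, Mapping[Proteoform, float]]]],
    manifest: pd.DataFrame,
    family: str,
) -> pd.DataFrame:
    """Build a normalized abundance table from per-class apportioned quants.

    ``class_quants`` maps (sample, technical replicate) to a list of
    (class precursor intensity, {proteoform: fraction}).  Per replicate,
    proteoform abundance = intensity x fraction rescaled to sum to 100;
    technical replicates are then averaged.  Replicates with zero total
    intensity are excluded.
    """
    meta = manifest.drop_duplicates("sample").set_index("sample")[["condition", "tissue"]]
    rep_rows = []
    for (sample, replicate), quants in class_quants.items():
        raw: dict[str, float] = {}
        for intensity, fractions in quants:
            for p, frac in fractions.items():
                key = p.notation() if isinstance(p, Proteoform) else str(p)
                raw[key] = raw.get(key, 0.0) + intensity * frac
        total = sum(raw.values())
        if total <= 0:
            import logging

            logging.getLogger(__name__).warning(
                "sample %s replicate %s has zero intensity; excluded", sample, replicate
            )
            continue
        for notation, value in raw.items():
            rep_rows.append((sample, replicate, notation, 100.0 * value / total))
    if not rep_rows:
        raise ValueError("no replicate produced nonzero intensity")
    df = pd.DataFrame(rep_rows, columns=["sample", "replicate", "proteoform", "abundance_percent"])
    # average technical replicates after normalization
    df = (
        df.pivot_table(
            index=["sample", "proteoform"], values="abundance_percent", aggfunc="mean",
            fill_value=0.0, columns="replicate",
        )
        .mean(axis=1)
        .rename("abundance_percent")
        .reset_index()
    )
    df["family"] = family
    df = df.merge(meta, left_on="sample", right_index=True, how="left")
    # replicate-averaging of a union of proteoform sets can drift off 100
    sums = df.groupby("sample")["abundance_percent"].transform("sum")
    df["abundance_percent"] = df["abundance_percent"] / sums * 100.0
    return df[["family", "proteoform", "sample", "condition", "tissue", "abundance_percent"]]


def validate_abundance_table(table: pd.DataFrame) -> None:
    sums = table.groupby(["sample", "family"])["abundance_percent"].sum()
    bad = sums[(sums - 100.0).abs() > ABUNDANCE_SUM_TOL]
    if not bad.empty:
        raise ValueError(f"abundances do not sum to 100: {bad.to_dict()}")
    if (table["abundance_percent"] < 0).any():
        raise ValueError("negative abundance")


# ---------------------------------------------------------------------------
# Aggregation


def _as_query(query: str | Query) -> Query:
    return parse_notation(query) if isinstance(query, str) else query


def _match_mask(table: pd.DataFrame, query: Query, schema: SiteStateSchema) -> pd.Series:
    if query.family is not None and query.family != schema.family:
        raise ValueError(f"query family {query.family!r} != table family {schema.family!r}")
    cache: dict[str, bool] = {}

    def hit(notation: str) -> bool:
        if notation not in cache:
            p = realize_exact(parse_notation(notation), schema)
            cache[notation] = query.matches(
                Proteoform(schema.family, p.states) if query.family else p
            )
        return cache[notation]

    return table["proteoform"].map(hit)


def discrete_ptm(
    table: pd.DataFrame, query: str | Query, schema: SiteStateSchema
) -> pd.Series:
    """Per-sample summed abundance of proteoforms matching a query.

    For a ``{}`` query this is the paper-style discrete-PTM abundance; an
    exact ``<>`` query returns the single proteoform's abundance.
    """
    q = _as_query(query)
    if q.family is None:
        q = (
            ExactQuery(schema.family, q.states)
            if isinstance(q, ExactQuery)
            else ContainsQuery(schema.family, q.constraints)
        )
    sub = table[table["family"] == schema.family]
    mask = _match_mask(sub, q, schema)
    return (
        sub[mask].groupby("sample")["abundance_percent"].sum()
        .reindex(sub["sample"].unique(), fill_value=0.0)
    )


def bulk_metrics(table: pd.DataFrame, schema: SiteStateSchema) -> pd.DataFrame:
    """Per-sample bulk acetylation/methylation metrics.

    percent_acetylated: % of molecules with >= 1 side-chain acetyl;
    percent_methylated: % with >= 1 methylated lysine; acetyls/methyls per
    molecule: abundance-weighted mean mark counts (me2 counts 2 methyls).
    """
    validate_abundance_table(table)
    sub = table[table["family"] == schema.family].copy()
    info = {
        n: realize_exact(parse_notation(n), schema)
        for n in sub["proteoform"].unique()
    }
    sub["n_ac"] = sub["proteoform"].map(lambda n: info[n].n_acetyl())
    sub["n_me"] = sub["proteoform"].map(lambda n: info[n].n_methyl())
    g = sub.groupby("sample")

    def agg(d: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "percent_acetylated": d.loc[d.n_ac > 0, "abundance_percent"].sum(),
                "percent_methylated": d.loc[d.n_me > 0, "abundance_percent"].sum(),
                "acetyls_per_molecule": (d.abundance_percent * d.n_ac).sum() / 100.0,
                "methyls_per_molecule": (d.abundance_percent * d.n_me).sum() / 100.0,
            }
        )

    return g.apply(agg, include_groups=False)


# ---------------------------------------------------------------------------
# Comparison and statistics


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare(
    groups: Mapping[str, Sequence[float]],
    metric: str = "",
    thresholds: StatThresholds = StatThresholds(),
) -> ComparisonResult:
    """Compare a metric between 2 (Welch t) or 3 (ANOVA + Tukey) groups.

    pp and fold changes are computed from group means (fold = mean_a/mean_b).
    The significance flag requires both p < alpha and fold beyond the cutoff
    in either direction; with n < 2 in a group, tests are omitted and only
    descriptives are returned.
    """
    names = list(groups)
    if len(names) not in (2, 3):
        raise ValueError("compare expects 2 or 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    means = {k: float(v.mean()) for k, v in arrays.items()}
    can_test = all(len(v) >= 2 for v in arrays.values())

    anova_p = None
    tukey = None
    if len(names) == 3 and can_test:
        anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
        tukey = stats.tukey_hsd(*arrays.values())

    pairs = (
        [(0, 1)] if len(names) == 2 else [(0, 1), (0, 2), (1, 2)]
    )
    pairwise = []
    for ia, ib in pairs:
        a, b = names[ia], names[ib]
        fold = means[a] / means[b] if means[b] != 0 else np.inf
        if not can_test:
            p = None
        elif len(names) == 2:
            p = _welch_p(arrays[a], arrays[b])
        else:
            p = float(tukey.pvalue[ia, ib])
        sig = None
        if p is not None:
            sig = p < thresholds.alpha and (
                fold >= thresholds.fold_cutoff or fold <= 1.0 / thresholds.fold_cutoff
            )
        pairwise.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                mean_a=means[a],
                mean_b=means[b],
                pp_change=means[a] - means[b],
                fold_change=fold,
                p=p,
                significant=sig,
            )
        )
    return ComparisonResult(metric=metric, group_means=means, pairwise=pairwise, anova_p=anova_p)


def _check_pvalues(p: np.ndarray) -> None:
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Classic linear step-up rejection set at level alpha."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    passed = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passed.size:
        reject[order[: passed[-1] + 1]] = True
    return reject


def fdr_two_stage(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up FDR (Benjamini-Krieger-Yekutieli).

    Stage 1 runs the step-up at alpha' = alpha/(1+alpha) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns the step-up with the
    constant inflated by m/m0.  Returns (discovery flags, q-values) with
    q = BH-adjusted p x (1+alpha) x m0/m, the convention under which a
    discovery is exactly q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    alpha_prime = alpha / (1.0 + alpha)
    m0 = m - int(_bh_reject(p, alpha_prime).sum())
    q_raw = bh_adjust(p) * (1.0 + alpha) * m0 / m
    return q_raw <= alpha, np.minimum(q_raw, 1.0)
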