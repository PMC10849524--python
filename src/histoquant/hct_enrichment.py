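"""Consensome building and HCT (high-confidence transcriptional target)
footprint enrichment.

A consensome ranks a signaling node's candidate target genes by the mean
ChIP-seq peak strength across archived datasets; genes in the top 5% of the
ranking (the "95th percentile") form the node's HCT set.  A query gene set's
regulatory footprint for a node is the hypergeometric upper-tail probability
of its overlap with the node's HCTs, BH-corrected across nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation_stats import bh_adjust

HCT_PERCENTILE = 95.0


@dataclass(frozen=True)
class ConsensomeNode:
    node: str
    genes: tuple[str, ...]  # ranked, best first
    scores: tuple[float, ...]
    percentiles: tuple[float, ...]  # in (0, 100]; ties share the best value
    hct: frozenset[str]


@dataclass
class EnrichmentResult:
    node: str
    overlap: int  # k
    gene_set_size: int  # n
    hct_size: int  # K
    universe_size: int  # N
    odds_ratio: float
    p: float
    q: float = float("nan")


@dataclass(frozen=True)
class ThermoNodeSet:
    """Nodes annotated to thermoregulatory-deficit phenotypes."""

    nodes: frozenset[str]
    universe_size: int = 691


def build_consensome(
    node: str,
    dataset_scores: pd.DataFrame,
    hct_percentile: float = HCT_PERCENTILE,
) -> ConsensomeNode:
    """Rank genes by mean score across datasets and materialize the HCT set.

    ``dataset_scores`` needs columns (dataset, gene, score).  Percentile is
    100 * rank / n with max-rank tie handling, so tied genes share the best
    percentile of their run; HCT membership is percentile > hct_percentile.
    """
    if dataset_scores.empty:
        raise ValueError("empty gene score table")
    mean_scores = (
        dataset_scores.assign(gene=dataset_scores["gene"].str.casefold())
        .groupby("gene")["score"]
        .mean()
    )
    n = len(mean_scores)
    ranks = stats.rankdata(mean_scores.to_numpy(), method="max")
    pct = 100.0 * ranks / n
    order = np.argsort(-mean_scores.to_numpy(), kind="stable")
    genes = tuple(mean_scores.index[order])
    hct = frozenset(g for g, p in zip(mean_scores.index, pct) if p > hct_percentile)
    return ConsensomeNode(
        node=node,
        genes=genes,
        scores=tuple(mean_scores.to_numpy()[order]),
        percentiles=tuple(pct[order]),
        hct=hct,
    )


def hypergeom_upper_p(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b = k, n - k
    c, d = K - k, N - K - n + k
    if min(a, b, c, d) == 0:  # Haldane-Anscombe
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def hct_intersection(
    gene_set: Iterable[str],
    nodes: Sequence[ConsensomeNode],
    universe_genes: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric footprint of a gene set against each node's HCTs.

    Symbols are case-folded; genes outside the universe are dropped with a
    warning.  q-values are BH across nodes.
    """
    universe = frozenset(g.casefold() for g in universe_genes)
    query = {g.casefold() for g in gene_set}
    outside = query - universe
    if outside:
        import logging

        logging.getLogger(__name__).warning(
            "%d gene(s) outside universe dropped: %s",
            len(outside),
            sorted(outside)[:10],
        )
        query &= universe
    N, n = len(universe), len(query)
    results = []
    for node in nodes:
        hct = node.hct & universe
        K = len(hct)
        k = len(query & hct)
        results.append(
            EnrichmentResult(
                node=node.node,
                overlap=k,
                gene_set_size=n,
                hct_size=K,
                universe_size=N,
                odds_ratio=_odds_ratio(k, n, K, N),
                p=hypergeom_upper_p(k, N, K, n),
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def thermo_enrichment(
    ranked_nodes: Sequence[str],
    thermo: ThermoNodeSet,
    top_fraction: float,
) -> float:
    """Enrichment of thermoregulatory nodes among top-ranked footprint nodes.

    Takes the first ceil(top_fraction x len(ranked_nodes)) nodes and returns
    the hypergeometric upper-tail p for their thermo-node count, with the
    configured universe size and K = |thermo nodes|.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    top_n = math.ceil(top_fraction * len(ranked_nodes))
    top = set(ranked_nodes[:top_n])
    k = len(top & thermo.nodes)
    return hypergeom_upper_p(k, thermo.universe_size, len(thermo.nodes), top_n)
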