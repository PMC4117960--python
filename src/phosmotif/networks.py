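"""Interaction-network statistics for motif-bearing proteins.

Covers the motif-sharing graph (motifs linked when they occur in
sufficiently overlapping protein sets), the fold-change of induced
interaction counts against randomly drawn protein sets, the core/additional
partition of the signaling network (core = proteins with sites conserved to
the most distal species; additional = their one-hop neighbours), and the
odds-ratio / chi-square enrichment of sigmoid-motif proteins in the
additional network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import chi2

OVERLAP_RULES = ("union", "sum")


def shared_proportion(proteins_a: set, proteins_b: set, rule: str = "union") -> float:
    """Overlap of two motifs' protein sets.

    ``union``: |A∩B| / |A∪B| (Jaccard); ``sum``: |A∩B| / (|A| + |B|).
    """
    if not proteins_a or not proteins_b:
        raise ValueError("protein sets must be nonempty")
    inter = len(proteins_a & proteins_b)
    if rule == "union":
        return inter / len(proteins_a | proteins_b)
    if rule == "sum":
        return inter / (len(proteins_a) + len(proteins_b))
    raise ValueError(f"unknown overlap rule {rule!r}")


@dataclass(frozen=True)
class MotifShareEdge:
    motif_a: str
    motif_b: str
    proportion: float


def build_motif_graph(
    motif_proteins: Mapping[str, set],
    threshold: float = 0.2,
    rule: str = "union",
) -> list[MotifShareEdge]:
    """Edges between motifs whose protein overlap is strictly > threshold."""
    if not motif_proteins:
        raise ValueError("empty motif -> protein map")
    ids = sorted(motif_proteins)
    edges: list[MotifShareEdge] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if not motif_proteins[a] or not motif_proteins[b]:
                continue
            p = shared_proportion(motif_proteins[a], motif_proteins[b], rule)
            if p > threshold:
                edges.append(MotifShareEdge(a, b, p))
    return edges


@dataclass(frozen=True)
class FoldChange:
    observed_edges: int
    random_mean: float
    random_sd: float
    fold: float  # math.inf when the random mean is zero but edges observed


def induced_edge_count(network: nx.Graph, proteins: Iterable[str]) -> int:
    members = set(proteins) & set(network.nodes)
    return network.subgraph(members).number_of_edges()


def interaction_fold_change(
    network: nx.Graph,
    motif_proteins: set,
    n_rand: int = 100,
    seed: int = 0,
) -> FoldChange:
    """Observed induced edges over the mean of random same-size draws.

    Random sets are sampled uniformly without replacement from the
    network's node universe; proteins absent from the network contribute no
    edges but still count toward the sample size.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    observed = induced_edge_count(network, motif_proteins)
    rng = np.random.default_rng(seed)
    universe = sorted(network.nodes)
    k = min(len(motif_proteins), len(universe))
    counts = np.empty(n_rand, dtype=float)
    for i in range(n_rand):
        draw = rng.choice(universe, size=k, replace=False)
        counts[i] = network.subgraph(draw.tolist()).number_of_edges()
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_rand > 1 else 0.0
    if mean == 0.0:
        fold = 0.0 if observed == 0 else math.inf
    else:
        fold = observed / mean
    return FoldChange(observed, mean, sd, fold)


@dataclass(frozen=True)
class CoreAdditionalPartition:
    core: frozenset
    additional: frozenset

    def __post_init__(self) -> None:
        if self.core & self.additional:
            raise ValueError("core and additional must be disjoint")


def partition_core_additional(
    network: nx.Graph, core_proteins: set
) -> CoreAdditionalPartition:
    """Additional network = one-hop neighbours of the core, minus the core."""
    core = frozenset(core_proteins)
    additional: set = set()
    for p in core:
        if p in network:
            additional.update(network.neighbors(p))
    return CoreAdditionalPartition(core, frozenset(additional - core))


def chi_square_2x2(a: float, b: float, c: float, d: float,
                   yates: bool = False) -> tuple[float, float]:
    """Chi-square statistic and p-value for a 2x2 table (a,b / c,d).

    Without Yates correction this is exactly
    n*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); degenerate margins give (0, 1).
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0 or n <= 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class EnrichmentResult:
    """Sigmoid-vs-other by additional-vs-core 2x2 enrichment."""

    table: tuple[int, int, int, int]  # (a, b, c, d) as documented below
    odds_ratio: float
    correction_applied: bool
    chi_square: float
    p_value: float
    random_mean: float
    random_sd: float


def odds_ratio_2x2(a: float, b: float, c: float, d: float
                   ) -> tuple[float, bool]:
    """(a*d)/(b*c); adds 0.5 to every cell when any cell is zero."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c)), corrected


def sigmoid_enrichment(
    partition: CoreAdditionalPartition,
    sigmoid_proteins: set,
    n_rand: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Are sigmoid-motif proteins over-represented in the additional network?

    Builds the 2x2 table a = sigmoid in additional, b = sigmoid in core,
    c = other in additional, d = other in core; odds ratio (a*d)/(b*c) with
    a 0.5 continuity correction when any cell is zero, chi-square on the
    raw table.  The randomization baseline redraws ``n_rand`` uniform
    same-size protein sets from core+additional and reports the mean and sd
    of their additional-side counts.
    """
    core, additional = partition.core, partition.additional
    if not core and not additional:
        raise ValueError("both core and additional networks are empty")
    a = len(sigmoid_proteins & additional)
    b = len(sigmoid_proteins & core)
    c = len(additional) - a
    d = len(core) - b
    oddsr, corrected = odds_ratio_2x2(a, b, c, d)
    stat, p = chi_square_2x2(a, b, c, d)
    rng = np.random.default_rng(seed)
    universe = sorted(core | additional)
    k = min(len(sigmoid_proteins), len(universe))
    add_counts = np.empty(n_rand, dtype=float)
    additional_set = set(additional)
    for i in range(n_rand):
        draw = rng.choice(universe, size=k, replace=False)
        add_counts[i] = sum(1 for x in draw if x in additional_set)
    return EnrichmentResult(
        (a, b, c, d), oddsr, corrected, stat, p,
        float(add_counts.mean()),
        float(add_counts.std(ddof=1)) if n_rand > 1 else 0.0,
    )


def read_edge_list(rows: Iterable[tuple[str, str]]) -> nx.Graph:
    """Undirected graph from (a, b) pairs; self-loops and duplicates dropped."""
    g = nx.Graph()
    for a, b in rows:
        if a != b:
            g.add_edge(a, b)
    return g
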