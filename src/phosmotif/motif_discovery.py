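"""Phosphomotif discovery from annotated phosphosites.

The discovery stage slices fixed-geometry windows around each phosphosite,
scores all window pairs by summed BLOSUM62 entries, links pairs scoring
strictly above a threshold (default 9) into a similarity graph, partitions
the graph with Markov clustering, and derives one consensus pattern per
sufficiently large cluster.  Utilities for exact motif matching, coverage
statistics, C2H2 zinc-finger scanning and position frequency matrices live
here as well.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .core import (
    ACCEPTORS,
    AMINO_ACIDS,
    WINDOW_GEOMETRY,
    MotifPattern,
    blosum62,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceWindow:
    """A window of residues around one phospho-acceptor."""

    protein_id: str
    site_position: int  # 1-based position of the acceptor in the protein
    window_type: str
    residues: str
    anchor_offset: int

    def __post_init__(self) -> None:
        anchor, length = WINDOW_GEOMETRY[self.window_type]
        if len(self.residues) != length:
            raise ValueError(
                f"{self.window_type} window must be {length} residues"
            )
        if self.anchor_offset != anchor:
            raise ValueError("anchor offset inconsistent with window type")
        if self.residues[self.anchor_offset] not in ACCEPTORS:
            raise ValueError("window anchor must be S, T or Y")


def extract_windows(
    sequences: Mapping[str, str],
    phosphosites: pd.DataFrame,
    window_type: str,
    statuses: Iterable[str] = ("known",),
) -> list[SequenceWindow]:
    """One window per phosphosite whose span lies fully inside the protein.

    Sites whose span would cross a terminus are skipped (and counted in a
    log summary); an annotated residue that disagrees with the sequence is
    an error, as is a position outside the protein.
    """
    anchor, length = WINDOW_GEOMETRY[window_type]
    statuses = set(statuses)
    windows: list[SequenceWindow] = []
    skipped = 0
    for row in phosphosites.itertuples(index=False):
        if row.status not in statuses:
            continue
        seq = sequences.get(row.protein_id)
        if seq is None:
            raise KeyError(f"site references unknown protein {row.protein_id!r}")
        pos = int(row.position)
        if not (1 <= pos <= len(seq)):
            raise ValueError(
                f"site {row.protein_id}:{pos} outside protein of length {len(seq)}"
            )
        if seq[pos - 1] != row.residue:
            raise ValueError(
                f"site {row.protein_id}:{pos} annotated {row.residue} "
                f"but sequence has {seq[pos - 1]}"
            )
        start = pos - 1 - anchor
        if start < 0 or start + length > len(seq):
            skipped += 1
            continue
        windows.append(
            SequenceWindow(row.protein_id, pos, window_type,
                           seq[start:start + length], anchor)
        )
    if skipped:
        logger.info("%d sites skipped (window crosses a terminus)", skipped)
    return windows


def score_window_pair(a: SequenceWindow, b: SequenceWindow) -> int:
    """Summed BLOSUM62 score over aligned window positions; symmetric."""
    if a.window_type != b.window_type:
        raise ValueError("cannot score windows of different types")
    mat = blosum62()
    return sum(mat[(x, y)] for x, y in zip(a.residues, b.residues))


@dataclass
class SimilarityGraph:
    """Undirected window-similarity graph; edges score strictly > threshold."""

    graph: nx.Graph
    windows: list[SequenceWindow]
    threshold: int


def _blosum_array() -> tuple[np.ndarray, np.ndarray]:
    """(matrix over the 20+X alphabet, char->index lookup)."""
    alphabet = AMINO_ACIDS + "X"
    mat = blosum62()
    arr = np.array(
        [[mat[(a, b)] for b in alphabet] for a in alphabet], dtype=np.int32
    )
    lut = np.full(128, len(alphabet) - 1, dtype=np.int64)  # unknowns -> X
    for i, a in enumerate(alphabet):
        lut[ord(a)] = i
    return arr, lut


def build_similarity_graph(
    windows: Sequence[SequenceWindow], threshold: int = 9
) -> SimilarityGraph:
    """All-vs-all window scoring; keep pairs scoring strictly > threshold."""
    if windows and len({w.window_type for w in windows}) > 1:
        raise ValueError("all windows must share a window type")
    g = nx.Graph()
    g.add_nodes_from(range(len(windows)))
    if len(windows) > 1:
        arr, lut = _blosum_array()
        codes = np.array(
            [lut[np.frombuffer(w.residues.encode(), dtype=np.uint8)]
             for w in windows]
        )
        n, length = codes.shape
        scores = np.zeros((n, n), dtype=np.int32)
        for j in range(length):
            scores += arr[codes[:, j][:, None], codes[:, j][None, :]]
        ii, jj = np.nonzero(np.triu(scores > threshold, k=1))
        g.add_weighted_edges_from(
            (int(i), int(j), int(scores[i, j])) for i, j in zip(ii, jj)
        )
    return SimilarityGraph(g, list(windows), threshold)


@dataclass
class MCLResult:
    clusters: list[list[int]]
    converged: bool
    n_iter: int


def mcl_cluster(
    graph: SimilarityGraph | nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> MCLResult:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added (per-node max incident weight, 1 for isolated
    nodes), columns are normalised to a stochastic flow matrix, and
    expansion (matrix power) alternates with inflation (elementwise power
    followed by renormalisation) and pruning of entries below ``prune``
    until the matrix changes by less than ``tol`` or ``max_iter`` passes.
    Clusters are the connected components of the final flow support, which
    always partition the node set.
    """
    g = graph.graph if isinstance(graph, SimilarityGraph) else graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = list(g.nodes)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight",
                                 format="csr").astype(float)
    loops = np.asarray(a.max(axis=1).todense()).ravel()
    loops[loops <= 0] = 1.0
    m = (a + sp.diags(loops)).tocsc()

    def normalise(mat: sp.csc_matrix) -> sp.csc_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return (mat @ sp.diags(1.0 / colsum)).tocsc()

    m = normalise(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m.copy()
        power = m
        for _ in range(expansion - 1):
            power = power @ m
        m = power.tocsc()
        m.data **= inflation
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = normalise(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge after %d iterations", max_iter)
    support = (m > prune).astype(np.int8)
    support = support + support.T
    n_comp, labels = connected_components(support, directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        clusters[lab].append(nodes[idx])
    clusters.sort(key=lambda c: (min(c),))
    return MCLResult(clusters, converged, it)


@dataclass
class MotifCluster:
    cluster_id: str
    members: list[SequenceWindow]
    consensus: MotifPattern | None = None


def derive_consensus(
    members: Sequence[SequenceWindow],
    position_freq_threshold: float = 0.6,
    min_cluster_size: int = 3,
    motif_id: str = "",
) -> MotifPattern | None:
    """Automated consensus pattern for a window cluster.

    Each non-anchor position is fixed to its dominant residue when its
    frequency reaches the threshold, to {S,T} when serine plus threonine
    jointly reach it, and is a wildcard otherwise.  The anchor is fixed to
    the pooled set of observed acceptors.  Clusters below the minimum size
    yield no pattern.
    """
    if len(members) < min_cluster_size:
        return None
    wtypes = {m.window_type for m in members}
    if len(wtypes) != 1:
        raise ValueError("cluster members must share a window type")
    wtype = wtypes.pop()
    anchor, length = WINDOW_GEOMETRY[wtype]
    n = len(members)
    positions: list[frozenset | None] = []
    for j in range(length):
        counts: dict[str, int] = {}
        for w in members:
            counts[w.residues[j]] = counts.get(w.residues[j], 0) + 1
        if j == anchor:
            positions.append(frozenset(counts))
            continue
        top, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if top_n / n >= position_freq_threshold:
            positions.append(frozenset(top))
        elif (counts.get("S", 0) + counts.get("T", 0)) / n >= position_freq_threshold:
            positions.append(frozenset("ST"))
        else:
            positions.append(None)
    return MotifPattern(motif_id or "consensus", wtype, tuple(positions))


def discover_motifs(
    windows: Sequence[SequenceWindow],
    threshold: int = 9,
    inflation: float = 2.0,
    position_freq_threshold: float = 0.6,
    min_cluster_size: int = 3,
    **mcl_kwargs,
) -> tuple[list[MotifCluster], SimilarityGraph]:
    """Full discovery pass: graph, MCL, consensus per cluster."""
    graph = build_similarity_graph(windows, threshold)
    if not windows:
        return [], graph
    result = mcl_cluster(graph, inflation=inflation, **mcl_kwargs)
    clusters: list[MotifCluster] = []
    for k, idxs in enumerate(result.clusters):
        cid = f"c{k:03d}"
        mem = [windows[i] for i in idxs]
        consensus = derive_consensus(
            mem, position_freq_threshold, min_cluster_size, motif_id=f"m{k:03d}"
        )
        clusters.append(MotifCluster(cid, mem, consensus))
    return clusters, graph


def match_motif(sequence: str, pattern: MotifPattern) -> list[int]:
    """1-based anchor positions of every exact occurrence of the pattern."""
    length = len(pattern)
    out: list[int] = []
    for start in range(len(sequence) - length + 1):
        if pattern.matches(sequence[start:start + length]):
            out.append(start + pattern.anchor_offset + 1)
    return out


def site_is_covered(
    sequence: str, position: int, patterns: Sequence[MotifPattern]
) -> bool:
    """True if some pattern matches with its anchor at the 1-based site."""
    for pat in patterns:
        start = position - 1 - pat.anchor_offset
        if start < 0 or start + len(pat) > len(sequence):
            continue
        if pat.matches(sequence[start:start + len(pat)]):
            return True
    return False


@dataclass
class CoverageReport:
    """Fraction of phosphosites matched by at least one motif pattern."""

    covered_count: int
    total_count: int
    per_residue: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def percent(self) -> int:
        """Coverage as a percentage, rounded to the nearest integer."""
        return round(100.0 * self.covered_count / self.total_count)

    def residue_percent(self, residue: str) -> int | None:
        pair = self.per_residue.get(residue)
        if not pair or pair[1] == 0:
            return None
        return round(100.0 * pair[0] / pair[1])


def coverage_stats(
    phosphosites: pd.DataFrame,
    patterns: Sequence[MotifPattern],
    sequences: Mapping[str, str],
    statuses: Iterable[str] = ("known",),
) -> CoverageReport:
    """Coverage of the phosphosite table by a pattern set.

    A site counts as covered when at least one pattern matches with its
    anchor at the site.  The per-residue breakdown applies the same rule
    restricted to S, T and Y sites.
    """
    statuses = set(statuses)
    covered = total = 0
    per_res = {r: [0, 0] for r in "STY"}
    for row in phosphosites.itertuples(index=False):
        if row.status not in statuses:
            continue
        total += 1
        hit = site_is_covered(sequences[row.protein_id], int(row.position), patterns)
        covered += hit
        if row.residue in per_res:
            per_res[row.residue][1] += 1
            per_res[row.residue][0] += hit
    if total == 0:
        raise ValueError("no phosphosites to report coverage on")
    return CoverageReport(covered, total,
                          {r: (c, t) for r, (c, t) in per_res.items()})


@dataclass(frozen=True)
class C2H2Hit:
    """One C2H2 zinc-finger occurrence.

    The matched span runs from two residues before the first cysteine to
    the last histidine; length classes 23/24/25 differ only in the number
    of residues between the two histidines (3, 4 or 5).
    """

    protein_id: str
    start: int  # 1-based
    length_class: int
    first_position_tyrosine: int | None  # 1-based position, if the span starts with Y
    threonine_after_last_histidine: int | None  # 1-based, residue just past the span

    @property
    def end(self) -> int:
        return self.start + self.length_class - 1


_C2H2_RES = {
    23: re.compile(r"..C..C.{12}H.{3}H"),
    24: re.compile(r"..C..C.{12}H.{4}H"),
    25: re.compile(r"..C..C.{12}H.{5}H"),
}


def scan_c2h2(sequence: str, protein_id: str = "") -> list[C2H2Hit]:
    """Maximal non-overlapping C2H2 matches, shortest class first at a start."""
    hits: list[C2H2Hit] = []
    i = 0
    n = len(sequence)
    while i <= n - 23:
        for length in (23, 24, 25):
            if i + length > n:
                continue
            if _C2H2_RES[length].fullmatch(sequence, i, i + length):
                y1 = i + 1 if sequence[i] == "Y" else None
                t_pos = i + length + 1
                t24 = t_pos if t_pos <= n and sequence[t_pos - 1] == "T" else None
                hits.append(C2H2Hit(protein_id, i + 1, length, y1, t24))
                i += length
                break
        else:
            i += 1
    return hits


@dataclass
class PositionFrequencyMatrix:
    """Per-column residue counts over the 20-letter alphabet."""

    counts: np.ndarray  # shape (20, n_columns)
    n_sequences: int

    @property
    def frequencies(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(colsum > 0, self.counts / colsum, 0.0)

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information in bits: log2(20) minus Shannon entropy."""
        f = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=0)
        return np.log2(20.0) - h

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(AMINO_ACIDS),
            columns=[str(i + 1) for i in range(self.counts.shape[1])],
        )


def compute_pfm(sequences: Sequence[str]) -> PositionFrequencyMatrix:
    """Count matrix of equal-length sequences (e.g. aligned 11-mers)."""
    if not sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    length = lengths.pop()
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, length), dtype=np.int64)
    for s in sequences:
        for j, ch in enumerate(s):
            i = idx.get(ch)
            if i is not None:
                counts[i, j] += 1
    return PositionFrequencyMatrix(counts, len(sequences))
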