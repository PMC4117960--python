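"""Cross-species conservation of phosphosites and motifs.

A human phosphosite is mapped into its ortholog-group alignment and called
conserved in a species when that species carries an S/T/Y residue at the
aligned column (the literal rule; a class-matched variant keeps S and T
interchangeable but requires Y to stay Y).  The distal-closure rule then
propagates conservation toward human: a site conserved in a species more
distant than q is regarded as conserved in q even when the intermediate
residue has drifted.  Per-species conservation rates (C_q), reference rates
over all human S/T/Y residues (R_q), the conservation index
S = sum_q (C_q - R_q), adjacent-species transition vectors, the
sigmoid/linear classifier and Ward profile clustering all build on those
calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import ACCEPTORS, GAP, GroupIndex, MotifPattern, OrthologGroup, SpeciesLadder

logger = logging.getLogger(__name__)

MODES = ("any_STY", "class_matched", "motif_exact")
LEVELS = ("site", "protein", "ortholog_group")


def map_site_column(group: OrthologGroup, human_position: int,
                    human: str = "hsa") -> int:
    """1-based alignment column of the human residue at an ungapped position."""
    member = group.member(human)
    if member is None:
        raise ValueError(f"group {group.group_id} has no {human} member")
    seen = 0
    for col, ch in enumerate(member.aligned_seq, start=1):
        if ch != GAP:
            seen += 1
            if seen == human_position:
                return col
    raise ValueError(
        f"position {human_position} beyond {human} sequence of length {seen} "
        f"in group {group.group_id}"
    )


def residue_conserved(
    group: OrthologGroup,
    column: int,
    species: str,
    mode: str = "any_STY",
    human: str = "hsa",
    valid_species: Sequence[str] | None = None,
) -> bool:
    """Is the aligned residue of *species* at *column* a conserved acceptor?

    ``any_STY`` (the default, literal rule): any of S, T, Y counts.
    ``class_matched``: S and T are interchangeable; a human Y is conserved
    only by a Y.  A gap, or a species absent from the group, is not
    conserved; with paralogs, any member of the species may conserve the
    site.
    """
    if valid_species is not None and species not in valid_species:
        raise KeyError(f"unknown species {species!r}")
    members = group.members_for(species)
    if not members:
        return False
    if mode not in ("any_STY", "class_matched"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    if mode == "class_matched":
        hm = group.member(human)
        href = hm.aligned_seq[column - 1] if hm else None
        allowed = frozenset("Y") if href == "Y" else frozenset("ST")
    else:
        allowed = ACCEPTORS
    return any(m.aligned_seq[column - 1] in allowed for m in members)


def distal_closure(raw: Sequence[bool], ladder: SpeciesLadder | None = None
                   ) -> np.ndarray:
    """Propagate conservation toward human (booleans ordered distal-first).

    Species q is conserved iff raw conservation holds in q or in any more
    distal species, so the output is monotone non-decreasing toward human.
    Idempotent.
    """
    arr = np.asarray(raw, dtype=bool)
    return np.maximum.accumulate(arr)


@dataclass(frozen=True)
class ConservationProfile:
    """Species-ordered conservation rates C_q for one motif (distal first)."""

    motif_id: str
    species: tuple[str, ...]
    rates: tuple[float, ...]
    n_human_sites: int

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rates):
            raise ValueError("one rate per species required")
        for r in self.rates:
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference rates R_q over all human residues of a class (distal first)."""

    residue_class: str  # one of S, T, Y, STY
    species: tuple[str, ...]
    rates: tuple[float, ...]
    n_human_sites: int


@dataclass(frozen=True)
class ConservationIndex:
    motif_id: str
    value: float


@dataclass(frozen=True)
class PatternCall:
    motif_id: str
    call: str  # "sigmoid" or "linear"
    acquisition_species: str | None
    rule: str
    threshold: float


def _site_vector(
    protein_id: str,
    position: int,
    index: GroupIndex,
    ladder: SpeciesLadder,
    mode: str,
    pattern: MotifPattern | None = None,
) -> np.ndarray:
    """Closed per-species conservation booleans for one human site.

    A protein without an ortholog group is conserved in human only.  In
    ``motif_exact`` mode a species conserves the site only when, besides an
    acceptor at the anchor column, the species' ungapped sequence contains a
    full match of the motif pattern.
    """
    n = len(ladder)
    raw = np.zeros(n, dtype=bool)
    raw[-1] = True  # the human site itself
    hit = index.get(protein_id)
    if hit is not None:
        group, _member = hit
        col = map_site_column(group, position, ladder.human)
        exact_cache: dict[str, bool] = {}
        for i, sp in enumerate(ladder.species[:-1]):
            base_mode = "any_STY" if mode == "motif_exact" else mode
            ok = residue_conserved(group, col, sp, base_mode, ladder.human)
            if ok and mode == "motif_exact" and pattern is not None:
                if sp not in exact_cache:
                    from .motif_discovery import match_motif

                    exact_cache[sp] = any(
                        match_motif(m.ungapped, pattern)
                        for m in group.members_for(sp)
                    )
                ok = exact_cache[sp]
            raw[i] = ok
    return distal_closure(raw)


def _aggregate(
    vectors: Mapping[object, np.ndarray], n_species: int
) -> tuple[np.ndarray, int]:
    """Pool per-unit boolean vectors into rates (units already deduplicated)."""
    n_units = len(vectors)
    stacked = np.zeros(n_species, dtype=float)
    for v in vectors.values():
        stacked += v
    return stacked / n_units, n_units


def _unit_key(level: str, protein_id: str, position: int, index: GroupIndex):
    if level == "site":
        return (protein_id, position)
    if level == "protein":
        return protein_id
    if level == "ortholog_group":
        hit = index.get(protein_id)
        return hit[0].group_id if hit else protein_id
    raise ValueError(f"unknown counting level {level!r}")


def conservation_profile(
    pattern: MotifPattern | str,
    sites: Iterable[tuple[str, int]],
    index: GroupIndex,
    ladder: SpeciesLadder,
    mode: str = "any_STY",
    level: str = "site",
) -> ConservationProfile:
    """Per-species conservation rates of the sites assigned to one motif.

    ``level`` chooses the counting unit: individual sites, proteins
    (multiple sites per protein counted once) or ortholog groups (paralogs
    counted once).  A unit is conserved in q when any of its sites is,
    after distal closure.
    """
    motif_id = pattern.id if isinstance(pattern, MotifPattern) else str(pattern)
    pat = pattern if isinstance(pattern, MotifPattern) else None
    vectors: dict[object, np.ndarray] = {}
    n_sites = 0
    for protein_id, position in sites:
        n_sites += 1
        v = _site_vector(protein_id, position, index, ladder, mode, pat)
        key = _unit_key(level, protein_id, position, index)
        vectors[key] = np.maximum(vectors[key], v) if key in vectors else v
    if n_sites == 0:
        raise ValueError(f"no sites assigned to motif {motif_id!r}")
    rates, n_units = _aggregate(vectors, len(ladder))
    return ConservationProfile(
        motif_id, ladder.species, tuple(float(r) for r in rates), n_units
    )


def reference_profile(
    sites: pd.DataFrame,
    index: GroupIndex,
    ladder: SpeciesLadder,
    mode: str = "any_STY",
    residue_class: str = "STY",
    level: str = "site",
) -> ReferenceProfile:
    """Reference rates over all human S/T/Y residues of one class.

    ``sites`` is a phosphosite table (known and potential rows pooled);
    ``residue_class`` restricts to S, T, Y or the pooled class STY.
    """
    wanted = set(residue_class)
    sub = sites[sites["residue"].isin(wanted)]
    if sub.empty:
        raise ValueError(f"no residues of class {residue_class!r} in table")
    vectors: dict[object, np.ndarray] = {}
    for row in sub.itertuples(index=False):
        v = _site_vector(row.protein_id, int(row.position), index, ladder, mode)
        key = _unit_key(level, row.protein_id, int(row.position), index)
        vectors[key] = np.maximum(vectors[key], v) if key in vectors else v
    rates, n_units = _aggregate(vectors, len(ladder))
    return ReferenceProfile(
        residue_class, ladder.species, tuple(float(r) for r in rates), n_units
    )


def conservation_index(
    c: ConservationProfile, r: ReferenceProfile
) -> ConservationIndex:
    """S = sum over non-human genomes q of (C_q - R_q).

    The human genome is excluded from the sum; both rates are 1 there, so
    including it would change nothing.
    """
    if c.species != r.species:
        raise ValueError("profiles computed on different ladders")
    value = float(
        sum(cq - rq for cq, rq, sp in zip(c.rates, r.rates, c.species)
            if sp != c.species[-1])
    )
    return ConservationIndex(c.motif_id, value)


def transitions(profile: ConservationProfile | Sequence[float]) -> np.ndarray:
    """Adjacent-species rate differences, closer-to-human minus more distal."""
    rates = np.asarray(
        profile.rates if isinstance(profile, ConservationProfile) else profile,
        dtype=float,
    )
    return np.diff(rates)


def classify_pattern(
    profile: ConservationProfile,
    rule: str = "jump50",
    k: float = 2.0,
    cohort: Sequence[ConservationProfile] | None = None,
) -> PatternCall:
    """Call a motif sigmoid or linear from its conservation profile.

    ``jump50``: sigmoid iff the maximal adjacent-species transition is
    strictly greater than 0.5.  ``mean_sd``: the threshold is mean + k*sd of
    all transitions pooled over the cohort of motifs.  The acquisition
    species is the closer-to-human species of the maximal transition pair;
    ties break toward the more distal pair.
    """
    t = transitions(profile)
    if rule == "jump50":
        threshold = 0.5
    elif rule == "mean_sd":
        if cohort is None:
            raise ValueError("mean_sd rule needs the motif cohort")
        pool = np.concatenate([transitions(p) for p in cohort])
        threshold = float(pool.mean() + k * pool.std(ddof=0))
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    jmax = int(np.argmax(t))  # first (most distal) maximal transition
    if t[jmax] > threshold:
        return PatternCall(profile.motif_id, "sigmoid",
                           profile.species[jmax + 1], rule, threshold)
    return PatternCall(profile.motif_id, "linear", None, rule, threshold)


def cluster_profiles(
    profiles: Sequence[ConservationProfile],
) -> np.ndarray:
    """Agglomerative clustering of rate vectors (Euclidean, Ward linkage).

    Returns the scipy linkage matrix; cut with :func:`cut_profiles`.
    Deterministic for a given input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    x = np.array([p.rates for p in profiles], dtype=float)
    return linkage(x, method="ward", metric="euclidean")


def cut_profiles(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels at ``k`` clusters from a linkage matrix."""
    return fcluster(merge_tree, t=k, criterion="maxclust")


@dataclass(frozen=True)
class CategoryCurve:
    category: str
    profile: ConservationProfile
    transition: tuple[float, ...]


def category_transition_profiles(
    sites: Iterable[tuple[str, int]],
    category_map: Mapping[str, str],
    index: GroupIndex,
    ladder: SpeciesLadder,
    mode: str = "any_STY",
    level: str = "site",
) -> dict[str, CategoryCurve]:
    """Pooled conservation rates and transition curves per protein category.

    An ``all`` control pooling every site is always included.  Categories
    with no sites are skipped with a warning.
    """
    sites = list(sites)
    by_cat: dict[str, list[tuple[str, int]]] = {}
    for pid, pos in sites:
        cat = category_map.get(pid)
        if cat is not None:
            by_cat.setdefault(cat, []).append((pid, pos))
    for cat in set(category_map.values()) - set(by_cat):
        warnings.warn(f"category {cat!r} has no sites; skipped")
    by_cat["all"] = sites
    out: dict[str, CategoryCurve] = {}
    for cat in sorted(by_cat):
        prof = conservation_profile(cat, by_cat[cat], index, ladder, mode, level)
        out[cat] = CategoryCurve(cat, prof,
                                 tuple(float(x) for x in transitions(prof)))
    return out


def assign_sites_to_pattern(
    pattern: MotifPattern,
    phosphosites: pd.DataFrame,
    sequences: Mapping[str, str],
    statuses: Iterable[str] = ("known",),
) -> list[tuple[str, int]]:
    """Known sites whose window matches the pattern anchored at the site."""
    from .motif_discovery import site_is_covered

    statuses = set(statuses)
    out = []
    for row in phosphosites.itertuples(index=False):
        if row.status not in statuses:
            continue
        seq = sequences.get(row.protein_id)
        if seq and site_is_covered(seq, int(row.position), [pattern]):
            out.append((row.protein_id, int(row.position)))
    return out
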