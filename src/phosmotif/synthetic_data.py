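"""Seeded, ground-truthed synthetic inputs for the phosphomotif pipeline.

Generates multi-species ortholog groups by substitution-only evolution down
an ordered species ladder, plants phosphomotif instances whose conservation
begins at a chosen acquisition species (the "sigmoid" ground truth), and
wires an interaction network with a dense conserved core plus attached
periphery.  Every draw goes through a single numpy Generator, so identical
seeds and configs yield byte-identical fixtures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import (
    ACCEPTORS,
    AMINO_ACIDS,
    GAP,
    MotifPattern,
    GroupMember,
    OrthologGroup,
    SpeciesLadder,
    codes_to_seq,
    seq_to_codes,
    substitution_propensities,
)

logger = logging.getLogger(__name__)

NON_ACCEPTORS = "".join(a for a in AMINO_ACIDS if a not in ACCEPTORS)

SITE_COLUMNS = ["protein_id", "position", "residue", "status"]


@dataclass(frozen=True)
class MotifSpec:
    """A motif to plant, with its ground-truth acquisition species.

    ``conservation_noise`` is the probability that a planted site is lost
    (anchor replaced by a non-acceptor) in a species where it should be
    conserved; human instances are never lost.
    """

    pattern: MotifPattern
    n_instances: int
    acquisition_species: str
    conservation_noise: float = 0.0
    #: optional explicit anchor placements as (group_id, human 1-based position)
    placements: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if not (0.0 <= self.conservation_noise <= 1.0):
            raise ValueError("conservation_noise must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a fixture."""

    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    acquisition: dict[str, str] = field(default_factory=dict)
    true_alignments: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "planted_sites": [list(t) for t in self.planted_sites],
            "acquisition": self.acquisition,
            "true_alignments": self.true_alignments,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "SyntheticTruth":
        return cls(
            [(p, int(pos), m) for p, pos, m in obj["planted_sites"]],
            dict(obj["acquisition"]),
            dict(obj["true_alignments"]),
        )


@dataclass
class SyntheticBundle:
    ladder: SpeciesLadder
    groups: list[OrthologGroup]
    sites: pd.DataFrame
    network: nx.Graph
    truth: SyntheticTruth


def make_ladder(config: Mapping | None = None) -> SpeciesLadder:
    """Build a species ladder from a flat config mapping.

    Recognised keys: ``species`` (ordered list, most distant first, human
    last), ``branch_divergence`` (list of per-adjacent-pair substitution
    fractions, or a single number applied to every branch) and ``human``
    (code of the human genome, default ``hsa``).  With no config the
    default nine-species yeast-to-human ladder is returned.
    """
    if not config:
        return SpeciesLadder.default()
    species = tuple(config.get("species", ()))
    if not species:
        return SpeciesLadder.default()
    div = config.get("branch_divergence", 0.2)
    if isinstance(div, (int, float)):
        div = [float(div)] * (len(species) - 1)
    human = config.get("human", "hsa")
    return SpeciesLadder(species, tuple(float(d) for d in div), human)


def _mutate(codes: np.ndarray, divergence: float, rng: np.random.Generator,
            cum: np.ndarray) -> np.ndarray:
    """Per-site substitution of a coded sequence at the given rate.

    Substitution targets are drawn from BLOSUM62-derived exchange
    propensities (diagonal excluded), so replacements favour biochemically
    similar residues.  Gap positions (code -1) are left untouched.
    """
    out = codes.copy()
    hit = (rng.random(codes.size) < divergence) & (codes >= 0)
    idx = np.flatnonzero(hit)
    if idx.size:
        u = rng.random(idx.size)
        rows = cum[codes[idx]]
        out[idx] = (u[:, None] > rows).sum(axis=1)
    return out


def evolve_families(
    ladder: SpeciesLadder,
    n_families: int,
    length_range: tuple[int, int] = (80, 160),
    seed: int = 0,
    loss_prob: float = 0.0,
    indel_rate: float = 0.0,
) -> tuple[list[OrthologGroup], SyntheticTruth]:
    """Evolve ortholog groups outward from a human root sequence.

    Each group has one member per ladder species (non-human members dropped
    with probability ``loss_prob``).  Sequences evolve by independent
    per-site substitution along the chain human -> chimp -> ... -> yeast at
    the ladder's branch divergences, so the residue-level alignment is the
    identity map.  With ``indel_rate`` > 0 a short deletion (gap run of 1-3
    columns) may additionally be applied per branch; the column map is
    unchanged because deletions are recorded as gap characters.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = length_range
    if lo < 30:
        raise ValueError("sequence length must be >= 30")
    rng = np.random.default_rng(seed)
    cum, _ = substitution_propensities()
    n_sp = len(ladder)
    groups: list[OrthologGroup] = []
    truth = SyntheticTruth()
    for f in range(n_families):
        gid = f"g{f:04d}"
        length = int(rng.integers(lo, hi + 1))
        seqs = np.empty((n_sp, length), dtype=np.int8)
        seqs[-1] = rng.integers(0, len(AMINO_ACIDS), size=length, dtype=np.int8)
        for i in range(n_sp - 2, -1, -1):
            child = _mutate(seqs[i + 1], ladder.branch_divergence[i], rng, cum)
            if indel_rate > 0.0 and rng.random() < indel_rate:
                span = int(rng.integers(1, 4))
                start = int(rng.integers(0, max(1, length - span)))
                child[start:start + span] = -1
            seqs[i] = child
        members = []
        for i, sp in enumerate(ladder.species):
            if sp != ladder.human and loss_prob > 0.0 and rng.random() < loss_prob:
                continue
            members.append(GroupMember(sp, f"{gid}_{sp}", codes_to_seq(seqs[i])))
        groups.append(OrthologGroup(gid, tuple(members)))
        truth.true_alignments[gid] = "identity"
    return groups, truth


def _human_column_map(aligned: str) -> np.ndarray:
    """0-based alignment column of each ungapped human position."""
    return np.flatnonzero(np.frombuffer(aligned.encode(), dtype=np.uint8)
                          != ord(GAP))


def plant_motif_instances(
    groups: Sequence[OrthologGroup],
    specs: Sequence[MotifSpec],
    ladder: SpeciesLadder,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[OrthologGroup], pd.DataFrame, SyntheticTruth]:
    """Write motif instances into the families and emit the phosphosite table.

    For each instance the realised pattern is written into the human
    sequence and into every species from the acquisition species toward
    human (minus ``conservation_noise`` losses); in more distal species the
    anchor residue is replaced by a non-acceptor.  Planted human anchors are
    emitted with status ``known``; every other human S/T/Y residue with
    status ``potential``.
    """
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth()
    # mutable working copy: group -> species member -> list of chars
    work: dict[str, dict[str, list[str]]] = {}
    meta: dict[str, dict[str, str]] = {}  # group -> species -> protein id
    colmaps: dict[str, np.ndarray] = {}
    for g in groups:
        work[g.group_id] = {}
        meta[g.group_id] = {}
        for m in g.members:
            work[g.group_id][m.species] = list(m.aligned_seq)
            meta[g.group_id][m.species] = m.protein_id
        hm = g.member(ladder.human)
        if hm is not None:
            colmaps[g.group_id] = _human_column_map(hm.aligned_seq)

    occupied: dict[str, set[int]] = {g.group_id: set() for g in groups}
    anchors: dict[tuple[str, int], str] = {}
    known_rows: list[tuple[str, int, str, str]] = []

    candidates = [g for g in groups if g.member(ladder.human) is not None]
    if not candidates:
        raise ValueError("no group has a human member")

    for spec in specs:
        pat = spec.pattern
        acq_idx = ladder.index(spec.acquisition_species)
        length = len(pat)
        truth.acquisition[pat.id] = spec.acquisition_species
        check_overlap = spec.placements is not None
        if spec.placements is not None:
            placements = list(spec.placements)
        else:
            placements = []
            tries = 0
            while len(placements) < spec.n_instances:
                tries += 1
                if tries > 200 * spec.n_instances:
                    raise RuntimeError(
                        f"could not place {spec.n_instances} instances of "
                        f"{pat.id}; sequences too short or too crowded"
                    )
                g = candidates[int(rng.integers(0, len(candidates)))]
                cmap = colmaps[g.group_id]
                n_h = cmap.size
                # keep a margin so all three window geometries fit around the anchor
                lo = pat.anchor_offset + 6
                hi = n_h - (length - pat.anchor_offset) - 5
                if hi <= lo:
                    continue
                anchor_pos = int(rng.integers(lo, hi + 1))  # 0-based human index
                start = anchor_pos - pat.anchor_offset
                cols = cmap[start:start + length]
                if occupied[g.group_id].intersection(cols.tolist()):
                    continue
                occupied[g.group_id].update(int(c) for c in cols)
                placements.append((g.group_id, anchor_pos + 1))
        for gid, human_pos in placements:
            g_work = work[gid]
            cmap = colmaps[gid]
            anchor_col = int(cmap[human_pos - 1])
            start = human_pos - 1 - pat.anchor_offset
            if start < 0 or start + length > cmap.size:
                raise ValueError(
                    f"pattern {pat.id} does not fit at {gid}:{human_pos}"
                )
            cols = [int(c) for c in cmap[start:start + length]]
            if check_overlap and (
                (gid, human_pos) in anchors or anchor_col in occupied[gid]
            ):
                raise ValueError(
                    f"overlapping planted instances at {gid} position {human_pos}"
                )
            human_seq = g_work[ladder.human]
            # realise the pattern once; wildcards keep the evolved human residue
            realised: list[str | None] = []
            for j, allowed in enumerate(pat.positions):
                if allowed is None:
                    realised.append(None)
                elif len(allowed) == 1:
                    realised.append(next(iter(allowed)))
                else:
                    choices = sorted(allowed)
                    realised.append(choices[int(rng.integers(0, len(choices)))])
            for j, res in enumerate(realised):
                if res is not None:
                    human_seq[cols[j]] = res
            anchor_res = human_seq[anchor_col]
            for i, sp in enumerate(ladder.species):
                if sp == ladder.human or sp not in g_work:
                    continue
                seq = g_work[sp]
                if i >= acq_idx:
                    if rng.random() < spec.conservation_noise:
                        if seq[anchor_col] != GAP:
                            seq[anchor_col] = NON_ACCEPTORS[
                                int(rng.integers(0, len(NON_ACCEPTORS)))
                            ]
                    else:
                        for j, res in enumerate(realised):
                            if res is not None and seq[cols[j]] != GAP:
                                seq[cols[j]] = res
                else:
                    if seq[anchor_col] != GAP:
                        seq[anchor_col] = NON_ACCEPTORS[
                            int(rng.integers(0, len(NON_ACCEPTORS)))
                        ]
            occupied[gid].update(cols)
            anchors[(gid, human_pos)] = pat.id
            pid = meta[gid][ladder.human]
            truth.planted_sites.append((pid, human_pos, pat.id))
            known_rows.append((pid, human_pos, anchor_res, "known"))

    rebuilt = [
        OrthologGroup(
            g.group_id,
            tuple(
                GroupMember(m.species, m.protein_id,
                            "".join(work[g.group_id][m.species]))
                for m in g.members
            ),
        )
        for g in groups
    ]

    rows = list(known_rows)
    known_keys = {(p, pos) for p, pos, _, _ in known_rows}
    for g in rebuilt:
        hm = g.member(ladder.human)
        if hm is None:
            continue
        seq = hm.ungapped
        for i, ch in enumerate(seq):
            if ch in ACCEPTORS and (hm.protein_id, i + 1) not in known_keys:
                rows.append((hm.protein_id, i + 1, ch, "potential"))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    sites = sites.sort_values(["protein_id", "position"], kind="mergesort")
    sites = sites.reset_index(drop=True)
    return rebuilt, sites, truth


def simulate_network(
    groups: Sequence[OrthologGroup],
    truth: SyntheticTruth,
    ladder: SpeciesLadder,
    params: Mapping | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Interaction network with a dense conserved core and attached periphery.

    Proteins whose planted motifs are conserved to the most distal ladder
    species form the core (pairwise edge probability ``core_density``);
    proteins with later acquisition attach to each core member with
    probability ``periphery_attach_prob``; ``n_extra`` unplanted human
    proteins each attach to one uniformly chosen core member.
    """
    params = dict(params or {})
    core_density = float(params.get("core_density", 0.3))
    attach = float(params.get("periphery_attach_prob", 0.08))
    n_extra = int(params.get("n_extra", 40))
    for name, p in (("core_density", core_density), ("periphery_attach_prob", attach)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    most_distal = ladder.species[0]
    core: set[str] = set()
    periphery: set[str] = set()
    for pid, _pos, motif_id in truth.planted_sites:
        if truth.acquisition.get(motif_id) == most_distal:
            core.add(pid)
        else:
            periphery.add(pid)
    periphery -= core
    planted = core | periphery
    unplanted = sorted(
        m.protein_id
        for g in groups
        for m in g.members_for(ladder.human)
        if m.protein_id not in planted
    )
    extras = list(
        rng.choice(unplanted, size=min(n_extra, len(unplanted)), replace=False)
    ) if unplanted and n_extra > 0 else []

    net = nx.Graph()
    net.add_nodes_from(sorted(core))
    net.add_nodes_from(sorted(periphery))
    net.add_nodes_from(extras)
    core_sorted = sorted(core)
    for i, a in enumerate(core_sorted):
        for b in core_sorted[i + 1:]:
            if rng.random() < core_density:
                net.add_edge(a, b)
    for p in sorted(periphery):
        for c in core_sorted:
            if rng.random() < attach:
                net.add_edge(p, c)
    for x in extras:
        if core_sorted:
            c = core_sorted[int(rng.integers(0, len(core_sorted)))]
            net.add_edge(x, c)
    return net


def default_motif_specs(
    n_instances: int = 30, conservation_noise: float = 0.05
) -> tuple[MotifSpec, ...]:
    """The study conditions: one yeast-to-human ("linear") motif plus three
    motifs acquired at the worm, fly and fish rungs ("sigmoid")."""
    mk = lambda s: MotifPattern.from_string(s, "centered7")
    return (
        MotifSpec(mk("KKDTEDE"), n_instances, "sce", conservation_noise),
        MotifSpec(mk("RRASPLG"), n_instances, "cel", conservation_noise),
        MotifSpec(mk("PPPSPKK"), n_instances, "dme", conservation_noise),
        MotifSpec(mk("DEEYEEV"), n_instances, "dre", conservation_noise),
    )


def generate_bundle(
    ladder: SpeciesLadder | None = None,
    n_families: int = 200,
    length_range: tuple[int, int] = (80, 160),
    specs: Sequence[MotifSpec] | None = None,
    network_params: Mapping | None = None,
    seed: int = 0,
    loss_prob: float = 0.0,
    indel_rate: float = 0.0,
) -> SyntheticBundle:
    """Run the full generator: families -> planted sites -> network."""
    ladder = ladder or SpeciesLadder.default()
    specs = default_motif_specs() if specs is None else specs
    ss = np.random.SeedSequence(seed)
    s_evolve, s_plant, s_net = (int(s.generate_state(1)[0] % 2**31)
                                for s in ss.spawn(3))
    groups, truth = evolve_families(
        ladder, n_families, length_range, seed=s_evolve,
        loss_prob=loss_prob, indel_rate=indel_rate,
    )
    groups, sites, truth = plant_motif_instances(
        groups, specs, ladder, seed=s_plant, truth=truth
    )
    network = simulate_network(groups, truth, ladder, network_params, seed=s_net)
    return SyntheticBundle(ladder, groups, sites, network, truth)


def emit_fixture(bundle: SyntheticBundle, directory: str | Path) -> list[Path]:
    """Write a bundle to disk as plain-text files.

    Layout: ``proteome.fasta`` (headers ``proteinID|species``),
    ``alignments/<group>.afa``, ``phosphosites.tsv``, ``interactions.tsv``,
    ``truth.json`` and ``ladder.yaml``.  Round-trips losslessly through
    :mod:`phosmotif.pipeline` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not bundle.groups:
        logger.warning("emitting fixture with no ortholog groups")

    fasta = directory / "proteome.fasta"
    with fasta.open("w") as fh:
        for g in sorted(bundle.groups, key=lambda g: g.group_id):
            for m in g.members:  # ladder order, as generated
                fh.write(f">{m.protein_id}|{m.species}\n{m.ungapped}\n")
    written.append(fasta)

    adir = directory / "alignments"
    adir.mkdir(exist_ok=True)
    for g in sorted(bundle.groups, key=lambda g: g.group_id):
        p = adir / f"{g.group_id}.afa"
        with p.open("w") as fh:
            for m in g.members:
                fh.write(f">{m.protein_id}|{m.species}\n{m.aligned_seq}\n")
        written.append(p)

    sites_path = directory / "phosphosites.tsv"
    bundle.sites.to_csv(sites_path, sep="\t", index=False)
    written.append(sites_path)

    edges_path = directory / "interactions.tsv"
    edges = sorted(tuple(sorted(e)) for e in bundle.network.edges())
    with edges_path.open("w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
    written.append(edges_path)

    truth_path = directory / "truth.json"
    truth_path.write_text(
        json.dumps(bundle.truth.to_json(), indent=1, sort_keys=True) + "\n"
    )
    written.append(truth_path)

    ladder_path = directory / "ladder.yaml"
    ladder_path.write_text(yaml.safe_dump({
        "species": list(bundle.ladder.species),
        "branch_divergence": [float(d) for d in bundle.ladder.branch_divergence],
        "human": bundle.ladder.human,
    }, sort_keys=True))
    written.append(ladder_path)
    return written
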