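"""End-to-end orchestration: simulate -> discover -> conserve -> network.

This module owns every file format the package reads or writes (FASTA,
aligned FASTA, TSV tables, JSON) and the flat pipeline configuration whose
defaults carry the analysis constants: similarity threshold 9, MCL
inflation 2.0, 50% transition jump, 20% motif-sharing threshold, 100
randomizations, 0.5 odds-ratio correction.  All user-facing coordinates are
1-based inclusive; floats are written with six significant digits and rows
are deterministically sorted, so identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import conservation as cons
from . import motif_discovery as disc
from . import networks as nets
from .core import GroupIndex, GroupMember, MotifPattern, OrthologGroup, SpeciesLadder, human_sequences
from .synthetic_data import (
    SITE_COLUMNS,
    SyntheticBundle,
    SyntheticTruth,
    emit_fixture,
    generate_bundle,
    make_ladder,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults are the analysis constants."""

    seed: int = 0
    window_types: tuple[str, ...] = ("centered7",)
    similarity_threshold: int = 9
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    mcl_prune: float = 1e-5
    consensus_freq_threshold: float = 0.6
    min_cluster_size: int = 3
    conservation_mode: str = "any_STY"
    conservation_level: str = "site"
    sigmoid_rule: str = "jump50"
    sigmoid_k: float = 2.0
    motif_graph_threshold: float = 0.2
    overlap_rule: str = "union"
    n_rand: int = 100
    # synthetic-data stage (used by simulate / run-all)
    n_families: int = 200
    length_range: tuple[int, int] = (80, 160)
    loss_prob: float = 0.0
    indel_rate: float = 0.0
    network_params: dict = field(default_factory=dict)
    ladder: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.similarity_threshold < 0:
            raise ValueError("similarity threshold must be >= 0")
        if not (0.0 < self.consensus_freq_threshold <= 1.0):
            raise ValueError("consensus threshold must be in (0, 1]")
        if not (0.0 <= self.motif_graph_threshold < 1.0):
            raise ValueError("motif graph threshold must be in [0, 1)")
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        for wt in self.window_types:
            if wt not in disc.WINDOW_GEOMETRY:
                raise ValueError(f"unknown window type {wt!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("window_types", "length_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def make_ladder(self) -> SpeciesLadder:
        return make_ladder(self.ladder)


# ---------------------------------------------------------------------------
# readers

def read_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read ``>proteinID|species`` FASTA; returns (sequences, species tags)."""
    seqs: dict[str, str] = {}
    species: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"{path}: record {rec.id!r} does not parse as proteinID|species"
            )
        pid, sp = rec.id.rsplit("|", 1)
        seqs[pid] = str(rec.seq)
        species[pid] = sp
    return seqs, species


def read_alignments(directory: str | Path,
                    valid_species: Sequence[str] | None = None
                    ) -> list[OrthologGroup]:
    """Read one aligned FASTA per ortholog group from a directory."""
    directory = Path(directory)
    groups: list[OrthologGroup] = []
    for path in sorted(directory.glob("*.afa")):
        gid = path.stem
        members = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"{path}: record {rec.id!r} does not parse as proteinID|species"
                )
            pid, sp = rec.id.rsplit("|", 1)
            if valid_species is not None and sp not in valid_species:
                raise ValueError(
                    f"{path}: species {sp!r} of {pid!r} not in the ladder"
                )
            members.append(GroupMember(sp, pid, str(rec.seq)))
        try:
            groups.append(OrthologGroup(gid, tuple(members)))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return groups


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str,
                                            "status": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    return df[SITE_COLUMNS]


def read_edges(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return nets.read_edge_list(
        (str(r.protein_a), str(r.protein_b)) for r in df.itertuples(index=False)
    )


def read_ladder(path: str | Path) -> SpeciesLadder:
    return make_ladder(yaml.safe_load(Path(path).read_text()))


def read_motifs(path: str | Path) -> list[MotifPattern]:
    data = json.loads(Path(path).read_text())
    return [MotifPattern.from_json(obj) for obj in data]


def read_inputs(directory: str | Path) -> SyntheticBundle:
    """Load and cross-validate a fixture directory.

    Checks: site protein ids exist in the FASTA, annotated residues match
    the sequences, alignment species codes are ladder members, alignments
    are rectangular.
    """
    directory = Path(directory)
    ladder = read_ladder(directory / "ladder.yaml")
    seqs, species = read_fasta(directory / "proteome.fasta")
    groups = read_alignments(directory / "alignments", ladder.species)
    sites = read_sites(directory / "phosphosites.tsv")
    network = read_edges(directory / "interactions.tsv")
    truth_path = directory / "truth.json"
    truth = (SyntheticTruth.from_json(json.loads(truth_path.read_text()))
             if truth_path.exists() else SyntheticTruth())
    for i, row in enumerate(sites.itertuples(index=False), start=2):
        if row.protein_id not in seqs:
            raise ValueError(
                f"phosphosites.tsv line {i}: unknown protein {row.protein_id!r}"
            )
        seq = seqs[row.protein_id]
        if not (1 <= row.position <= len(seq)) or seq[row.position - 1] != row.residue:
            raise ValueError(
                f"phosphosites.tsv line {i}: {row.protein_id}:{row.position} "
                f"does not carry residue {row.residue}"
            )
    return SyntheticBundle(ladder, groups, sites, network, truth)


# ---------------------------------------------------------------------------
# writers

def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# stages

@dataclass
class DiscoveryResult:
    clusters: dict[str, list[disc.MotifCluster]]  # per window type
    patterns: list[MotifPattern]
    coverage: disc.CoverageReport
    c2h2_hits: list[disc.C2H2Hit]


def run_discovery(bundle: SyntheticBundle, config: PipelineConfig
                  ) -> DiscoveryResult:
    sequences = human_sequences(bundle.groups, bundle.ladder.human)
    clusters: dict[str, list[disc.MotifCluster]] = {}
    patterns: list[MotifPattern] = []
    for wtype in config.window_types:
        windows = disc.extract_windows(sequences, bundle.sites, wtype)
        cl, _graph = disc.discover_motifs(
            windows,
            threshold=config.similarity_threshold,
            inflation=config.mcl_inflation,
            position_freq_threshold=config.consensus_freq_threshold,
            min_cluster_size=config.min_cluster_size,
            expansion=config.mcl_expansion,
            max_iter=config.mcl_max_iter,
            tol=config.mcl_tol,
            prune=config.mcl_prune,
        )
        for c in cl:
            c.cluster_id = f"{wtype}_{c.cluster_id}"
            if c.consensus is not None:
                c.consensus = dataclasses.replace(
                    c.consensus, id=f"{wtype}_{c.consensus.id}"
                )
                patterns.append(c.consensus)
        clusters[wtype] = cl
    coverage = disc.coverage_stats(bundle.sites, patterns, sequences)
    hits = [
        h
        for pid in sorted(sequences)
        for h in disc.scan_c2h2(sequences[pid], pid)
    ]
    return DiscoveryResult(clusters, patterns, coverage, hits)


def write_discovery(res: DiscoveryResult, out: Path) -> list[Path]:
    written = []
    rows = [
        (c.cluster_id, w.protein_id, w.site_position, w.residues)
        for cl in res.clusters.values()
        for c in cl
        for w in c.members
    ]
    written.append(_write_tsv(
        pd.DataFrame(rows, columns=["cluster_id", "protein_id", "position",
                                    "window"]),
        out / "clusters.tsv",
    ))
    (out / "motifs.json").write_text(
        json.dumps([p.to_json() for p in res.patterns], indent=1,
                   sort_keys=True) + "\n"
    )
    written.append(out / "motifs.json")
    cov = res.coverage
    cov_rows = [("all", cov.covered_count, cov.total_count, cov.percent)]
    for r in "STY":
        c, t = cov.per_residue.get(r, (0, 0))
        cov_rows.append((r, c, t, cov.residue_percent(r)))
    written.append(_write_tsv(
        pd.DataFrame(cov_rows, columns=["residues", "covered", "total",
                                        "percent"]),
        out / "coverage.tsv",
    ))
    written.append(_write_tsv(
        pd.DataFrame(
            [(h.protein_id, h.start, h.length_class,
              h.first_position_tyrosine, h.threonine_after_last_histidine)
             for h in res.c2h2_hits],
            columns=["protein_id", "start", "length_class", "y1_position",
                     "t_after_last_h"],
        ),
        out / "c2h2_hits.tsv",
    ))
    pfm_rows = []
    for cl in res.clusters.values():
        for c in cl:
            if c.consensus is None:
                continue
            pfm = disc.compute_pfm([w.residues for w in c.members])
            for i, aa in enumerate(disc.AMINO_ACIDS):
                pfm_rows.append((c.consensus.id, aa,
                                 *pfm.counts[i].tolist()))
    if pfm_rows:
        ncol = len(pfm_rows[0]) - 2
        written.append(_write_tsv(
            pd.DataFrame(pfm_rows, columns=["motif_id", "residue",
                                            *[f"p{i+1}" for i in range(ncol)]]),
            out / "pfms.tsv",
        ))
    return written


@dataclass
class ConservationResult:
    assignments: dict[str, list[tuple[str, int]]]
    profiles: dict[str, cons.ConservationProfile]
    references: dict[str, cons.ReferenceProfile]
    indices: dict[str, cons.ConservationIndex]
    calls: dict[str, cons.PatternCall]
    linkage: np.ndarray | None


def run_conservation(bundle: SyntheticBundle, patterns: Sequence[MotifPattern],
                     config: PipelineConfig) -> ConservationResult:
    sequences = human_sequences(bundle.groups, bundle.ladder.human)
    index = GroupIndex(bundle.groups)
    ladder = bundle.ladder
    assignments: dict[str, list[tuple[str, int]]] = {}
    profiles: dict[str, cons.ConservationProfile] = {}
    references: dict[str, cons.ReferenceProfile] = {}
    indices: dict[str, cons.ConservationIndex] = {}
    ref_cache: dict[str, cons.ReferenceProfile] = {}
    mode = ("any_STY" if config.conservation_mode == "motif_exact"
            else config.conservation_mode)
    for pat in patterns:
        assigned = cons.assign_sites_to_pattern(pat, bundle.sites, sequences)
        if not assigned:
            logger.warning("motif %s matches no known site; skipped", pat.id)
            continue
        assignments[pat.id] = assigned
        prof = cons.conservation_profile(
            pat if config.conservation_mode == "motif_exact" else pat.id,
            assigned, index, ladder,
            config.conservation_mode, config.conservation_level,
        )
        profiles[pat.id] = prof
        rc = "".join(sorted(pat.anchor_set))
        if rc not in ref_cache:
            ref_cache[rc] = cons.reference_profile(
                bundle.sites, index, ladder, mode, rc,
                config.conservation_level,
            )
        references[pat.id] = ref_cache[rc]
        indices[pat.id] = cons.conservation_index(prof, ref_cache[rc])
    cohort = list(profiles.values())
    calls = {
        mid: cons.classify_pattern(prof, config.sigmoid_rule,
                                   config.sigmoid_k, cohort)
        for mid, prof in profiles.items()
    }
    link = cons.cluster_profiles(cohort) if len(cohort) >= 2 else None
    return ConservationResult(assignments, profiles, references, indices,
                              calls, link)


def write_conservation(res: ConservationResult, ladder: SpeciesLadder,
                       out: Path) -> list[Path]:
    written = []
    prof_rows = [
        (mid, *prof.rates, prof.n_human_sites)
        for mid, prof in sorted(res.profiles.items())
    ]
    written.append(_write_tsv(
        pd.DataFrame(prof_rows, columns=["motif_id", *ladder.species,
                                         "n_units"]),
        out / "profiles.tsv",
    ))
    written.append(_write_tsv(
        pd.DataFrame(
            [(mid, idx.value) for mid, idx in sorted(res.indices.items())],
            columns=["motif_id", "conservation_index"],
        ),
        out / "index.tsv",
    ))
    pair_names = [f"{a}->{b}"
                  for a, b in zip(ladder.species, ladder.species[1:])]
    written.append(_write_tsv(
        pd.DataFrame(
            [(mid, *cons.transitions(prof))
             for mid, prof in sorted(res.profiles.items())],
            columns=["motif_id", *pair_names],
        ),
        out / "transitions.tsv",
    ))
    written.append(_write_tsv(
        pd.DataFrame(
            [(mid, c.call, c.acquisition_species or "", c.rule, c.threshold)
             for mid, c in sorted(res.calls.items())],
            columns=["motif_id", "call", "acquisition_species", "rule",
                     "threshold"],
        ),
        out / "pattern_calls.tsv",
    ))
    if res.linkage is not None:
        written.append(_write_tsv(
            pd.DataFrame(res.linkage,
                         columns=["left", "right", "height", "size"]),
            out / "linkage.tsv",
        ))
    return written


@dataclass
class NetworkResult:
    motif_edges: list[nets.MotifShareEdge]
    fold_changes: dict[str, nets.FoldChange]
    partition: nets.CoreAdditionalPartition
    enrichment: nets.EnrichmentResult | None
    core_proteins: frozenset
    sigmoid_proteins: frozenset


def run_network(bundle: SyntheticBundle, conserve: ConservationResult,
                config: PipelineConfig, seed: int | None = None
                ) -> NetworkResult:
    seed = config.seed if seed is None else seed
    index = GroupIndex(bundle.groups)
    ladder = bundle.ladder
    motif_proteins = {
        mid: {pid for pid, _pos in sites}
        for mid, sites in conserve.assignments.items()
    }
    motif_edges = (nets.build_motif_graph(motif_proteins,
                                          config.motif_graph_threshold,
                                          config.overlap_rule)
                   if motif_proteins else [])
    fold_changes = {
        mid: nets.interaction_fold_change(bundle.network, prots,
                                          config.n_rand, seed)
        for mid, prots in sorted(motif_proteins.items())
    }
    # core = proteins with a known site conserved in the most distal species
    core: set[str] = set()
    known = bundle.sites[bundle.sites["status"] == "known"]
    mode = ("any_STY" if config.conservation_mode == "motif_exact"
            else config.conservation_mode)
    for row in known.itertuples(index=False):
        hit = index.get(row.protein_id)
        if hit is None:
            continue
        group, _ = hit
        col = cons.map_site_column(group, int(row.position), ladder.human)
        if cons.residue_conserved(group, col, ladder.species[0], mode,
                                  ladder.human):
            core.add(row.protein_id)
    partition = nets.partition_core_additional(bundle.network, core)
    sigmoid = frozenset(
        pid
        for mid, call in conserve.calls.items()
        if call.call == "sigmoid"
        for pid in motif_proteins.get(mid, ())
    )
    enrichment = None
    if partition.core or partition.additional:
        enrichment = nets.sigmoid_enrichment(partition, set(sigmoid),
                                             config.n_rand, seed)
    return NetworkResult(motif_edges, fold_changes, partition, enrichment,
                         frozenset(core), sigmoid)


def write_network(res: NetworkResult, out: Path) -> list[Path]:
    written = []
    written.append(_write_tsv(
        pd.DataFrame(
            [(e.motif_a, e.motif_b, e.proportion) for e in res.motif_edges],
            columns=["motif_a", "motif_b", "proportion"],
        ),
        out / "motif_graph.tsv",
    ))
    written.append(_write_tsv(
        pd.DataFrame(
            [(mid, fc.observed_edges, fc.random_mean, fc.random_sd, fc.fold)
             for mid, fc in sorted(res.fold_changes.items())],
            columns=["motif_id", "observed_edges", "random_mean", "random_sd",
                     "fold"],
        ),
        out / "fold_change.tsv",
    ))
    part_rows = [(p, "core") for p in sorted(res.partition.core)]
    part_rows += [(p, "additional") for p in sorted(res.partition.additional)]
    written.append(_write_tsv(
        pd.DataFrame(part_rows, columns=["protein_id", "network"]),
        out / "partition.tsv",
    ))
    if res.enrichment is not None:
        e = res.enrichment
        payload = {
            "table": {"sigmoid_additional": e.table[0],
                      "sigmoid_core": e.table[1],
                      "other_additional": e.table[2],
                      "other_core": e.table[3]},
            "odds_ratio": e.odds_ratio,
            "correction_applied": e.correction_applied,
            "chi_square": e.chi_square,
            "p_value": e.p_value,
            "random_mean_additional": e.random_mean,
            "random_sd_additional": e.random_sd,
        }
        (out / "enrichment.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n"
        )
        written.append(out / "enrichment.json")
    return written


# ---------------------------------------------------------------------------
# the full pipeline

@dataclass
class RunReport:
    parameters: dict
    counts: dict
    manifest: list[str]

    def to_json(self) -> dict:
        return {"parameters": self.parameters, "counts": self.counts,
                "manifest": self.manifest}


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 input_dir: str | Path | None = None) -> RunReport:
    """Execute simulate (unless *input_dir* is given), discover, conserve
    and network, writing every stage's tables under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    if input_dir is None:
        bundle = generate_bundle(
            ladder=config.make_ladder(),
            n_families=config.n_families,
            length_range=config.length_range,
            network_params=config.network_params,
            seed=config.seed,
            loss_prob=config.loss_prob,
            indel_rate=config.indel_rate,
        )
        fixture_dir = out / "fixture"
        manifest += emit_fixture(bundle, fixture_dir)
    else:
        bundle = read_inputs(input_dir)

    discovery = run_discovery(bundle, config)
    manifest += write_discovery(discovery, out)
    conserve = run_conservation(bundle, discovery.patterns, config)
    manifest += write_conservation(conserve, bundle.ladder, out)
    network = run_network(bundle, conserve, config)
    manifest += write_network(network, out)

    report = RunReport(
        parameters=dataclasses.asdict(config),
        counts={
            "n_groups": len(bundle.groups),
            "n_known_sites": int((bundle.sites["status"] == "known").sum()),
            "n_potential_sites": int(
                (bundle.sites["status"] == "potential").sum()),
            "n_clusters": sum(len(c) for c in discovery.clusters.values()),
            "n_motifs": len(discovery.patterns),
            "coverage_percent": discovery.coverage.percent,
            "n_c2h2_hits": len(discovery.c2h2_hits),
            "n_sigmoid_motifs": sum(
                1 for c in conserve.calls.values() if c.call == "sigmoid"),
            "n_core_proteins": len(network.partition.core),
            "n_additional_proteins": len(network.partition.additional),
        },
        manifest=sorted(str(p.relative_to(out)) for p in manifest),
    )
    (out / "run_report.json").write_text(
        json.dumps(report.to_json(), indent=1, sort_keys=True) + "\n"
    )
    for rel in report.manifest:
        if not (out / rel).exists():  # pragma: no cover - sanity check
            raise RuntimeError(f"manifest file missing: {rel}")
    return report
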