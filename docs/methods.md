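# Methods

## Scope and model

The package implements a comparative phosphomotif analysis in four stages:
synthetic-data generation, motif discovery, conservation profiling and
network statistics. The underlying model is that functionally important
phosphorylation motifs are conserved above the background conservation of
serine/threonine/tyrosine residues, and that a motif acquired at a specific
speciation event shows a step ("sigmoid") conservation profile: absent in
species more distant than the acquisition species, present from there to
human.

Species are handled as an ordered ladder (most distant first, human last);
the order is an input assumption, not something the package estimates. The
default ladder is sce, spo, cel, dme, dre, cfa, mmu, ptr, hsa.

## Motif discovery

* Window geometry: upstream6 (five residues upstream plus the acceptor),
  centered7 (three on either side) and downstream6 (acceptor plus five
  downstream). Windows crossing a protein terminus are skipped, not padded:
  padding would require inventing substitution scores for absent residues.
  An X-padding variant can be built by the caller via the X column of
  BLOSUM62, which is exposed.
* Pair scores sum the BLOSUM62 entry at each aligned window position,
  including the acceptor position. Windows are compared only within a
  window type, anchors aligned. Edges require a score strictly greater than
  the threshold (default 9). The BLOSUM62 matrix comes from biopython and
  is asserted bit-exact against published entries in the tests.
* Clustering is an in-house Markov clustering (MCL): self-loops (per-node
  max incident weight, 1 for isolated nodes), column normalisation, then
  alternating expansion (matrix square) and inflation (elementwise power
  2.0, renormalise) with pruning of entries below 1e-5 until the flow
  matrix changes by less than 1e-6 or 100 iterations pass. Clusters are the
  connected components of the final flow support, which always partition
  the nodes; non-convergence returns the current clustering with a warning.
  Each window type is clustered separately and reported per type.
* Consensus: a position is fixed to its dominant residue when its frequency
  reaches 0.6, to {S,T} when serine and threonine jointly reach it, else
  wildcard; the anchor is the pooled set of observed acceptors; clusters
  under 3 members yield no pattern. This automates what was historically a
  manual curation step, so absolute motif counts on real data are not
  comparable between curators.
* Coverage: a site is covered when at least one pattern matches with its
  anchor at the site; percentages are reported rounded to the nearest
  integer, with a per-residue (S/T/Y) breakdown.
* C2H2 zinc fingers are found by pattern scan — `x(2)-C-x(2)-C-x(12)-H-x(3..5)-H`,
  length classes 23/24/25 from two residues before the first cysteine to
  the last histidine — preferring the shortest class at a shared start and
  taking maximal non-overlapping matches. The C–C spacer is fixed at two
  residues; the three classes differ only between the histidines. Hits
  annotate the first-position tyrosine and the threonine immediately after
  the last histidine when present.
* Position frequency matrices count the 20 standard residues per column;
  information content is log2(20) minus the column's Shannon entropy, with
  no pseudocounts.

## Conservation

* A site is conserved in species q when q's aligned residue is S, T or Y
  (`any_STY`, the default and the literal reading of the rule). The
  `class_matched` mode keeps S/T interchangeable but requires Y to remain
  Y; it exists because the literal rule counts Y→S as conserved, which
  per-residue sequence logos of real motifs contradict. A `motif_exact`
  mode additionally requires a full pattern match in the species' sequence.
* Gaps and missing species count as not conserved; if a species has several
  paralogs in a group, any of them may conserve the site.
* Distal closure: conservation in a species more distant than q implies
  conservation in q; implemented as a cumulative maximum toward human, so
  closed profiles are monotone and closure is idempotent.
* Rates can be counted per site, per protein (multiple sites per protein
  counted once) or per ortholog group (paralogs counted once).
* The conservation index S sums C_q − R_q over the non-human genomes; the
  human term is identically zero, so the choice is cosmetic but stated.
  R_q uses the residue class of the motif's acceptor set (S, T, Y or a
  pooled class such as ST).
* Classification: `jump50` calls a motif sigmoid when its maximal
  adjacent-species transition exceeds 0.5 strictly; `mean_sd` derives the
  threshold as mean + k·sd (default k = 2.0) of all transitions pooled over
  the motif cohort — pooled rather than per-pair, because the per-pair
  statistics of the original rule are not specified. The acquisition
  species is the closer-to-human species of the maximal transition; ties
  break toward the more distal pair.
* Profile clustering uses scipy's Ward linkage on Euclidean distances and
  is checked in the tests against a brute-force Lance–Williams
  implementation.

## Networks

* Motif-sharing edges require overlap strictly above 0.2. The overlap rule
  defaults to Jaccard (|A∩B|/|A∪B|); a `sum` rule (|A∩B|/(|A|+|B|)) is
  available because the phrase "total number of proteins in the two motifs"
  is ambiguous between the two.
* Fold change: induced edge count of the motif's proteins divided by the
  mean induced edge count of (default 100) uniform random same-size draws
  from the network's node universe. The node universe (rather than the
  whole proteome) keeps the null well defined; proteins absent from the
  network contribute zero edges.
* Core/additional: the core is the set of proteins with a known site
  conserved in the most distal ladder species; the additional network is
  the core's one-hop neighbourhood minus the core. No multi-hop expansion.
* Enrichment: 2×2 table of sigmoid/other × additional/core; odds ratio
  (a·d)/(b·c) with 0.5 added to every cell only when a cell is zero;
  chi-square in the exact closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
  without Yates correction by default. The randomization baseline redraws
  same-size protein sets uniformly from core ∪ additional and reports the
  mean ± sd of their additional-side counts.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism:

* Families evolve outward from a human root by independent per-site
  substitution along the chain human → chimp → … → yeast, at per-branch
  divergences (defaults 0.01, 0.08, 0.10, 0.25, 0.35, 0.35, 0.40, 0.30
  from the ptr–hsa branch outward — fixed, realistic amino-acid divergence
  fractions rising with distance from human). Substitution targets follow
  BLOSUM62-derived exchange propensities (2^(score/2), diagonal excluded),
  keeping replacements biochemically plausible and self-consistent with the
  scoring stage. Evolution is substitution-only by default, so the true
  alignment is the identity map; an optional per-branch deletion (1–3 gap
  columns) is behind a config flag and leaves the column map intact.
* Motif planting writes a realised pattern into the human sequence and into
  every species from the acquisition species toward human; in more distal
  species the anchor is replaced by a non-acceptor. Conservation noise is
  the per-species probability of losing a planted site. Planted human
  anchors become `known` rows of the phosphosite table; all other human
  S/T/Y residues become `potential` rows. Overlapping explicit placements
  at one residue are an error; random placement rejects collisions.
* Default study conditions: 200 families of 80–160 residues, four fully
  fixed centered7 motifs × 30 instances at 5% noise — KKDTEDE acquired at
  sce (the "linear" control), RRASPLG at cel, PPPSPKK at dme, DEEYEEV at
  dre. The patterns are chosen so within-motif window pairs score well
  above the edge threshold and cross-motif pairs below it.
* The simulated network connects the sce-acquired proteins pairwise with
  probability `core_density` (0.3), attaches each later-acquisition protein
  to each core member with `periphery_attach_prob` (0.08), and attaches
  `n_extra` (40) unplanted proteins to one core member each.
* What this does not emulate: indel-heavy alignments, codon-level
  evolution, gene duplication, database ascertainment bias, or realistic
  interaction-network topology. Passing tests therefore demonstrate the
  correctness and calibration of the machinery under its own assumptions,
  not the reproduction of database-scale results, which depend on specific
  releases of the source databases.
* Missing orthologs (species dropped with `loss_prob`) count as not
  conserved; the level of counting (absent protein vs absent residue) is a
  config choice, not a claim about the original analysis.

## Numerical and interface choices

* All thresholds are strict where the source phrasing is strict: score > 9,
  transition > 50%, overlap > 20%.
* User-facing coordinates are 1-based inclusive; internal computation is
  0-based. Floats are written with six significant digits; rows are
  deterministically sorted; every stochastic step derives its generator
  from the configured seed, so identical config + seed gives byte-identical
  outputs.
* Problem sizes in the test suite and acceptance script (200 families,
  ≤ 1000 randomizations) were chosen as the smallest sizes at which the
  binomial/stochastic checks have comfortable margins (3 standard errors).

## Known limitations

* MCL cluster extraction via flow-support components is standard but can
  merge clusters connected by near-threshold flow; inflation and pruning
  are config-exposed.
* The automated consensus rule is a surrogate for manual curation; on real
  data the motif count is sensitive to the frequency threshold.
* The `mean_sd` classifier needs a motif cohort; with few motifs its
  threshold estimate is noisy.
* The sigmoid/linear dichotomy compresses profiles with several moderate
  jumps into "linear".
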