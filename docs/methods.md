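# Methods

## The model

`baculonet` treats a viral infection time course as evidence about a
directed gene regulatory network (GRN). The data are log10 relative
expression values for ~150 ORFs at 10 time points (0, 1, 3, 5, 7, 9, 11,
13, 24, 48 h post infection) in 3 independent infection replicates. Under
the assumption of a recurrent transcriptional program, the three 48-h
replicates are concatenated column-wise into one long series — three
successive infection cycles — which maximizes the gene-to-gene covariance
signal available to the learner. Non-detected measurements are stored at a
detection floor (0.0 on the log10 scale by default).

### Edge ranking

For every target gene *j*, an ensemble of regression trees predicts *j*'s
expression across samples from the same-sample expression of all other
genes; the weight of edge *i*→*j* is regulator *i*'s impurity
(variance-reduction) importance summed over the ensemble, normalized so
incoming weights per non-constant target sum to 1. Targets are scaled to
unit variance before fitting. Samples are treated as exchangeable
observations — the learner never sees the time axis — so the method infers
association structure, not temporal precedence; an optional `lag=1` design
(regulators at *t*, target at *t*+1 within each replicate) is exposed but
off by default.

Ensemble defaults are the tree-ensemble GRN method's published ones: 1000
trees, K = ⌈√(G−1)⌉ candidate regulators per split. One deliberate
deviation: bootstrap resampling is disabled and ensemble diversity comes
from feature subsampling alone. Bootstrap draws are keyed to row positions,
which would make edge weights depend on the (meaningless) ordering of
samples; without it the fitted ensemble is a function of the sample *set*,
and weights are invariant to sample permutation up to floating-point
tie-breaking in near-equal candidate splits (the test suite allows 0.02
absolute on normalized importances for this).

### Network assembly and pruning

Directed edges enter strictly in rank order until the undirected
projection first forms a single connected component over all genes;
everything up to that rank is kept, redundant edges included. Hub scores
are MNC (node count of the largest connected component induced by a node's
open neighborhood) and DMNC (that component's |E|/|V|^ε with ε = 1.7, the
hub-scoring tool's published default; the source analysis does not state
it). Pruning then removes edges in ascending weight order, skipping any
edge whose loss would disconnect the projection and any edge that is an
endpoint's last link to a top-quartile hub (mean of MNC and DMNC ranks),
until ≈ `target_ratio` (default 5) edges per node remain. The published
analysis names the hub statistics but not the pruning rule; this
weight-ascending, connectivity- and hub-protecting reconstruction is the
package's own and is the largest inferential gap in the reimplementation.
It reproduces the intended regime: a single component at ~5 edges per node.

### Topology and communities

All shortest-path statistics run on the unweighted undirected projection.
Betweenness is normalized by (n−1)(n−2)/2; stress counts geodesics through
a node once per unordered source–target pair. ACC(k) and ANC(k) are the
mean clustering coefficient and mean neighbor-degree over nodes of degree
k; their trend versus k is summarized by a least-squares slope weighted by
bin occupancy (√count), because singleton high-degree bins otherwise
dominate the fit with noise. Communities come from greedy agglomerative
modularity maximization (deterministic merge order), with Newman's
Q = Σ_c (e_cc − a_c²); community labels are renumbered by size for
reproducibility. The null model re-runs the entire pipeline — shuffle,
rank, assemble, prune, detect — on per-gene time-shuffled data and reports
the Q distribution with normal-approximation and percentile 99% upper
bounds. Per-gene shuffling (rather than one shared column permutation) is
the default because a shared permutation preserves gene–gene
cross-correlation and would not null the network signal.

Attribute enrichment per community uses the uncorrected Pearson 2×2 χ²
(df = 1). No continuity correction is applied; this convention reproduces
the published recomputable statistics (14.002, 4.900, 3.073, 4.047) from
their printed marginals exactly to the printed precision.

### Promoters, genome architecture, diversity

Upstream windows are 200 bp 5′ of the annotated start codon, on the gene's
sense strand, wrapping across the circular origin; coordinates are GenBank
style (1-based, inclusive). Late promoters are DTAAG (D ∈ {A,G,T});
early promoters are a TATA or TATAWWW box (W ∈ {A,T}) followed by CANT
anywhere downstream in the window — the source gives no spacing bound, so
none is the default and a `max_spacing` flag is exposed. An ambiguous N in
the genome matches only the N of CANT. Classes are mutually exclusive:
early, late, early_and_late, none.

Intergenic spacers are `next.start − current.end − 1` over consecutive
ORFs in circular order (negative = overlapping genes); the wrap-around
pair is included. The co-occurrence test estimates, by Monte Carlo over
uniform permutations of the attribute list (strands permuted jointly), the
probability of at least one circular run of ≥ k consecutive genes sharing
an attribute value; a linear mode reproduces origin-anchored variants, and
binomial standard errors are always reported. Runs on the circular order
are the default reading of "co-occurrence of tandem attributes" —
adjacency runs are the only operationalization consistent with
incrementing a counter when a sampled attribute equals the previous one.

Genetic diversity is the Watterson estimator θ_W = S/(a_{n−1}·L_eff) per
site, with S the segregating columns and a_{n−1} = Σ 1/i. The full
coalescent-MCMC refinement used downstream in the original analysis is out
of scope; θ_W is the statistic that MCMC is initialized with. Columns
containing any gap or ambiguity are excluded from both S and L_eff by
default (complete deletion); a pairwise-style rule is available. The
core-vs-satellite contrast reports group medians/means ± SE for θ and
betweenness, Mann-Whitney U p-values (the source does not name its test)
and the Spearman θ–centrality correlation.

## The synthetic data generator

The generator's defaults are the study conditions: 150 genes, 5 modules,
10 time points, 3 replicates, detection floor 0.0. The regulatory graph is
a directed planted partition (p_in = 0.15 within modules, p_out = 0.005
between), kept acyclic from earlier to later cascade ranks and rooted at a
single earliest driver gene so that every gene is reachable (which also
makes the graph one weak component). Modules double as temporal classes
with onsets (0, 3, 7, 10, 13) h and characteristic peak hours
(3, 9, 13, 24, 48) h: a gene's latent activity is zero before its
activation hour and then follows the transcript pulse
((Δt/c)·e^{1−Δt/c})^α with α = 3 — immediate-early transcripts rise and
decline as the viral polymerase takes over, late and very-late transcripts
accumulate to the end of the course. Activation propagates along
regulatory edges with geometrically shrinking delays bounded by a 2-h
within-class spread, so regulators always activate strictly before their
targets while classes keep distinct identities (the inter-class onset gap
is ≥ 3 h). Emitted values are peak·activity + N(0, 0.15²) on the log10
scale (peaks uniform in 2–4 log10 units), clipped at the detection floor.

The rise-and-fall pulse matters for inference: purely monotone saturating
profiles make every temporal class an invertible transform of every other,
which regression trees fit perfectly, erasing module identity. The pulse
shapes are non-invertible across classes, which is both the biologically
observed behavior of early transcripts and the property that makes the
planted modules statistically recoverable.

The synthetic genome lays ORFs on a circle with tandem-overlap ROT runs
(spacers −25 to −4 bp, shared strand) and positive spacers elsewhere;
minus-strand-to-plus-strand boundaries get ≥ 420 bp so that upstream
windows never collide. Each ORF's 200-bp window is written to carry
exactly its planted promoter class; in strict mode the background is
rejection-sampled to contain neither TATA nor DTAAG and the final window
is verified, so classification recovers planted classes with zero errors.
Alignments evolve a random root over a fixed 4-taxon tree (branch weights
0.2/0.2/0.1 per side, summing to 1) with per-site mutation probability
d·weight per branch, so d is the expected substitutions per site over the
tree and the expected segregating fraction is 1 − Π(1 − d·w_b) under the
infinite-sites approximation.

What the generator does **not** emulate: amplification-efficiency and
standard-curve error structure of real qPCR, gene-specific noise
heterogeneity, codon structure or rate variation in alignments,
transcription readthrough (ROTs are positional, not transcriptional), and
host-gene contributions. Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical power under a clean planted model,
not performance guarantees on real transcriptome data.

## Benchmark and problem sizes

The standing experiment (`baculonet.benchmark`) runs 20 paired
structured-vs-shuffled pipeline instances at full study scale (150 genes,
5 modules, 3 replicates) with 50-tree ensembles — at 30 samples the
importance estimates are stable well below the 1000-tree production
default, and the benchmark completes in minutes on one CPU. Scores per
arm: modularity Q, adjusted Rand index against planted modules,
precision-recall AUC of ranked weights against planted edges, ACC(k)
slope, and ranked edges consumed to reach one component.

Observed behavior under the defaults: structured Q ≈ 0.73–0.79 against a
shuffled-null 99% upper bound ≈ 0.70; mean ARI ≈ 0.97; PR-AUC wins 20/20.
One caveat is documented rather than hidden: under the shuffled null the
ranked importances are nearly exchangeable, the single component assembles
after only ~300–450 edges (≈2.3 edges/node, below the pruning target, so
pruning is inert), and the null networks' ACC(k) slope is a mean-zero
noise statistic with a slight positive bias. The package therefore does
not reproduce a *negative* clustering-degree dependence in its shuffled
nulls; on real data, heterogeneous qPCR marginals concentrate spurious
importance and yield denser, prunable null networks where that negative
trend was observed.

## Numerical conventions

* Ranked edge lists sort by weight descending, ties broken
  lexicographically on (regulator, target); all outputs are deterministic
  under a fixed seed, and every stochastic stage requires one.
* Zero-variance targets get all-zero incoming weights and a warning;
  all-degenerate null replicates raise instead of returning a Q.
* DMNC is 0 when the neighborhood component has < 2 nodes; ties among
  equal-sized neighborhood components break by edge count, then node ids.
* Q of the one-community partition is exactly 0; modularity is computed on
  the undirected projection with antiparallel edge pairs collapsed.
* Monte Carlo co-occurrence reports p̂ ± binomial SE; the default
  iteration count (10⁶) makes the SE ≤ 5·10⁻⁴ at worst.
* Mantel-style permutation p-values use (count + 1)/(n_perm + 1),
  one-sided for positive association.

## Known limitations

* The pruning rule is a reconstruction; published edge counts
  (765/991/713/727) are data-dependent and not reproducible without the
  replicate-level expression tables, which were never deposited.
* Stress-centrality pair-ordering (ordered vs unordered) differs between
  tools; this package counts unordered pairs once.
* The promoter tally and ROT membership checks against the real genome
  require the public GenBank record and supplementary interval table as
  local downloads; the repository ships neither.
* Watterson θ is a lower-level statistic than the coalescent-MCMC estimate
  it initializes; published θ values (0.42/0.47) are comparison references
  only.
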