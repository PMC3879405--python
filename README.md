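# baculonet

Gene-regulatory-network inference and genome-architecture statistics for
baculovirus qPCR expression time courses.

## The problem

The *Anticarsia gemmatalis* multiple nucleopolyhedrovirus (AgMNPV-2D) is a
large circular dsDNA insect virus whose genome encodes 152 predicted ORFs;
149 of them are expressed during infection of permissive cell lines and can
be followed by real-time PCR at 0–48 h post infection. From such an
ORF × time-point expression matrix one can ask system-level questions: does
the viral transcriptional program wire its genes into a *modular* regulatory
network, the way cellular networks are organized? Do the modules align with
gene function, promoter type (host-polymerase *early* elements vs the viral
*late* DTAAG element), physical gene order on the circular genome and
regions of overlapping transcription (ROTs)? And are topologically central
genes under stronger evolutionary constraint (lower genetic diversity)?

`baculonet` implements that entire analysis as a tested, reusable pipeline
for anyone working with compact viral transcriptomes:

1. **expression** — validated I/O for ORF × (replicate, time) log10
   expression tables, concatenation of replicates into one long series, and
   the per-gene time-shuffling null.
2. **grn** — tree-ensemble edge ranking: for each target gene a
   random-forest-style regressor predicts its expression from all other
   genes; normalized variance-reduction importances become confidence
   weights on directed regulator→target edges.
3. **netbuild** — ranked edges are added in order until a single connected
   component spans all genes; hubs are scored by MNC/DMNC (maximum
   neighborhood component and its density |E|/|V|^1.7) and the network is
   pruned, protecting connectivity and hub lifelines, to ≈5 edges per node.
4. **topology** — betweenness and stress centrality, clustering-coefficient
   (ACC) and neighbor-connectivity (ANC) profiles by degree with trend
   slopes, all validated against exhaustive brute-force oracles.
5. **communities** — greedy-modularity community detection, Newman's
   Q = Σ_c (e_cc − a_c²), a full-pipeline null-Q distribution on shuffled
   data, and uncorrected Pearson 2×2 χ² enrichment of node attributes per
   community.
6. **promoters** — strand-aware extraction of 200-bp upstream windows from
   the circular genome and rule-based classification: *late* = DTAAG
   (D ∈ {A,G,T}), *early* = TATA/TATAWWW box followed downstream by CANT,
   both, or none.
7. **spatial** — intergenic spacers and overlapping ORFs, ROT membership,
   Monte Carlo runs tests for attribute co-occurrence along the circular
   gene order, and expression-distance vs map-distance Mantel tests.
8. **diversity** — per-gene Watterson θ_W = S/(a_{n−1}·L) from small
   multiple alignments, and the core (replication/capsid) vs satellite
   contrast of diversity against betweenness centrality.
9. **synthetic** — ground-truthed generators for every input: a planted
   5-module regulatory cascade sampled on the real 10-point time grid in 3
   replicates, a circular genome with planted motifs and tandem-overlap ROT
   runs, and 4-taxon alignments with planted mutation densities.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_infer_network.py
```

prints, for the default simulated data set:

```
single component after 3576 ranked edges; pruned to 750 edges
5 communities, Q = 0.786
ACC(k) trend slope = +0.0046 (positive = clustering rises with degree)
adjusted Rand index vs planted modules = 1.000
```

That is the headline result in miniature: from expression alone, the
pipeline assembles a single 150-gene component, prunes it to ~5 edges per
node, and greedy modularity recovers the five planted regulatory modules
exactly (ARI 1.0) with Q ≈ 0.79. The null contrast
(`python analysis/03_null_contrast.py`, 20 paired runs) shows that
time-shuffled data — identical per-gene value distributions, no temporal
structure — yields Q with a 99% upper bound ≈ 0.70, well below the
structured mean 0.77, and that ranked edge weights recover planted edges
far better than the shuffled control (PR-AUC 0.066 vs 0.018, 20/20 paired
wins). `04_genome_architecture.py` and `05_diversity_vs_centrality.py`
cover the promoter, spatial and diversity analyses, including the
recomputed published enrichment χ² values (14.002, 4.900, 3.073, 4.047).

A `baculonet` CLI wraps the same library surface
(`baculonet simulate|load|infer|build|topology|communities|promoters|run`).

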