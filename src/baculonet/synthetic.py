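"""Ground-truthed generators for every input the pipeline consumes.

Four generators mirror the shapes of the real study inputs:

* a directed planted-partition regulatory network (~150 genes in 5
  modules, dense within and sparse between modules) whose modules double
  as temporal classes of the infection cascade (early modules switch on
  at 0-3 h, late ones at 7-13 h);
* a threshold-saturation expression cascade sampled on the real qPCR time
  grid (0-48 h post infection, 3 replicates, log10 scale with Gaussian
  noise and a detection floor);
* a circular genome with ORFs laid out in tandem overlapping runs (ROTs)
  and promoter motifs planted in each ORF's upstream window exactly
  matching its assigned class;
* per-gene 4-taxon alignments with a planted per-site mutation density.

Everything is bit-reproducible under a fixed seed, and every generator
returns its ground truth so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import DEFAULT_TIME_GRID, ExpressionSeries
from .netbuild import Network
from .promoters import GenomeRecord
from .spatial import GeneOrderAttributes, ROTTable

__all__ = [
    "SyntheticSpec",
    "GroundTruthNetwork",
    "generate_grn",
    "simulate_expression",
    "generate_genome",
    "generate_alignments",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the synthetic generators.

    Defaults mirror the real data shapes: ~150 genes in 5 regulatory
    modules sampled at 10 time points in 3 replicates, with module onsets
    spanning the early (0-3 h) to late (7-13 h) phases of the infection
    cascade.
    """

    n_genes: int = 150
    n_modules: int = 5
    p_in: float = 0.15
    p_out: float = 0.005
    onset_times: tuple = (0.0, 3.0, 7.0, 10.0, 13.0)
    peak_times: tuple = (3.0, 9.0, 13.0, 24.0, 48.0)
    time_grid: tuple = DEFAULT_TIME_GRID
    n_replicates: int = 3
    noise_sd: float = 0.15
    detection_floor: float = 0.0
    shape_alpha: float = 3.0  # sharpness of the rise-and-fall pulse
    class_spread: float = 2.0  # max activation spread within a class (h)
    peak_range: tuple = (2.0, 4.0)  # log10 peak expression
    # genome layout
    n_orfs: int = 60
    orf_length_range: tuple = (300, 1200)
    rot_runs: tuple = (4, 3, 4, 3)  # tandem overlapping runs
    promoter_proportions: dict = field(
        default_factory=lambda: {
            "late": 0.34, "early": 0.15, "early_and_late": 0.28, "none": 0.23
        }
    )
    # alignments
    n_alignment_genes: int = 50
    alignment_length: int = 2000
    mutation_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.onset_times) < self.n_modules:
            raise ValueError("need an onset time per module")
        tmax = max(self.time_grid)
        if any(t > tmax for t in self.onset_times[: self.n_modules]):
            raise ValueError("onsets must fall within the sampled time grid")
        if not 0.0 <= self.mutation_density <= 0.75:
            raise ValueError("mutation density must lie in [0, 0.75]")


@dataclass
class GroundTruthNetwork:
    """Planted regulatory network with module labels and onset hours."""

    network: Network
    module_of: dict[str, int]
    onset_of: dict[str, float]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.network.nodes)


def _gene_ids(n: int) -> list[str]:
    return [f"orf{k + 1:03d}" for k in range(n)]


def generate_grn(spec: SyntheticSpec) -> GroundTruthNetwork:
    """Directed planted-partition regulatory graph with temporal classes.

    Genes are split evenly over modules; each ordered pair gets an edge
    with probability ``p_in`` inside a module and ``p_out`` across
    modules.  Edges are kept acyclic (from lower to higher cascade rank,
    cross-module edges only from earlier-onset modules) so every
    regulator acts strictly before its targets; any gene left unreachable
    from the early seed module is attached to an upstream driver, making
    the whole cascade reachable from the earliest class.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    module_of = {g: i % spec.n_modules + 1 for i, g in enumerate(genes)}
    # cascade rank: module onset order first, then position within module
    onset = {m + 1: spec.onset_times[m] for m in range(spec.n_modules)}
    order = sorted(genes, key=lambda g: (onset[module_of[g]], g))
    rank = {g: i for i, g in enumerate(order)}

    edges: list[tuple[str, str, float]] = []
    for gi in genes:
        for gj in genes:
            if gi == gj or rank[gi] >= rank[gj]:
                continue
            p = spec.p_in if module_of[gi] == module_of[gj] else spec.p_out
            if rng.random() < p:
                edges.append((gi, gj, 1.0))

    # guarantee reachability from the earliest driver gene, which also
    # makes the cascade a single weakly connected component
    seeds = {order[0]}
    adjacency: dict[str, list[str]] = {g: [] for g in genes}
    for u, v, _ in edges:
        adjacency[u].append(v)
    reachable = set(seeds)
    stack = list(seeds)
    while stack:
        for v in adjacency[stack.pop()]:
            if v not in reachable:
                reachable.add(v)
                stack.append(v)
    existing = {(u, v) for u, v, _ in edges}
    for g in order:
        if g in reachable:
            continue
        candidates = [
            u for u in order
            if rank[u] < rank[g] and u in reachable and module_of[u] == module_of[g]
        ] or [u for u in order if rank[u] < rank[g] and u in reachable]
        if not candidates:
            raise ValueError("infeasible spec: no upstream driver available")
        u = candidates[int(rng.integers(len(candidates)))]
        if (u, g) not in existing:
            edges.append((u, g, 1.0))
            existing.add((u, g))
        # g and everything below it may now be reachable
        reachable.add(g)
        stack = [g]
        while stack:
            for v in adjacency[stack.pop()]:
                if v not in reachable:
                    reachable.add(v)
                    stack.append(v)

    net = Network(nodes=genes, edges=sorted(edges))
    onset_of = {g: onset[module_of[g]] for g in genes}
    return GroundTruthNetwork(network=net, module_of=module_of, onset_of=onset_of)


def _activation_times(truth: GroundTruthNetwork, spec: SyntheticSpec) -> dict[str, float]:
    """Onset hour per gene: class onset, delayed by cascade depth.

    A regulated gene switches on strictly after its latest regulator,
    but the propagation delays shrink geometrically toward the class
    onset + ``class_spread`` asymptote, so activation stays strictly
    ordered along every regulatory path while the within-class spread
    remains bounded below the gap between temporal classes.
    """
    import networkx as nx

    g = truth.network.digraph()
    t_act: dict[str, float] = {}
    for gene in nx.topological_sort(g):
        parents = list(g.predecessors(gene))
        onset = truth.onset_of[gene]
        t = onset
        if parents:
            latest = max(t_act[p] for p in parents)
            cap = onset + spec.class_spread
            t = max(onset, latest + 0.5 * (cap - latest))
        t_act[gene] = t
    return t_act


def simulate_expression(
    truth: GroundTruthNetwork, spec: SyntheticSpec
) -> list[ExpressionSeries]:
    """Sample the expression cascade on the time grid, one series per replicate.

    A gene's latent activity is zero before its activation hour (its
    class onset delayed by cascade depth, so regulators always rise
    before their targets) and then follows a rise-and-fall transcript
    pulse ``((dt/c) * exp(1 - dt/c))**alpha`` that peaks at the module's
    characteristic hour: immediate-early transcripts peak within hours
    and decline as the viral polymerase takes over, late and very-late
    ones keep accumulating to the end of the 48 h course.  The emitted
    value is ``peak * activity`` (log10 scale) plus Gaussian noise,
    clipped at the detection floor.  Replicates share everything but the
    noise draws.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = truth.gene_ids
    t_act = _activation_times(truth, spec)
    times = np.array(spec.time_grid, dtype=float)
    peaks = rng.uniform(*spec.peak_range, size=len(genes))
    onset = {m + 1: spec.onset_times[m] for m in range(spec.n_modules)}
    peak_at = {m + 1: spec.peak_times[m] for m in range(spec.n_modules)}

    latent = np.zeros((len(genes), times.size))
    for i, gene in enumerate(genes):
        m = truth.module_of[gene]
        rise = max(peak_at[m] - onset[m], 1.0)  # hours from activation to peak
        dt = times - t_act[gene]
        active = dt > 0
        x = dt[active] / rise
        latent[i, active] = peaks[i] * (x * np.exp(1.0 - x)) ** spec.shape_alpha

    series = []
    for rep in range(1, spec.n_replicates + 1):
        noisy = latent + rng.normal(0.0, spec.noise_sd, size=latent.shape)
        noisy = np.maximum(noisy, spec.detection_floor)
        series.append(
            ExpressionSeries(
                gene_ids=list(genes),
                sample_times=times.copy(),
                replicate_of=np.full(times.size, rep),
                values=noisy,
                cell_line="synthetic",
                detection_floor=spec.detection_floor,
            )
        )
    return series


# -- genome ---------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def _window_is_clean(seq: str) -> bool:
    """No accidental promoter signal: free of TATA and of DTAAG."""
    if "TATA" in seq:
        return False
    for i in range(len(seq) - 4):
        if seq[i] in "AGT" and seq[i + 1 : i + 5] == "TAAG":
            return False
    return True


def _clean_window(rng: np.random.Generator, length: int) -> str:
    for _ in range(200):
        seq = _random_seq(rng, length)
        if _window_is_clean(seq):
            return seq
    raise RuntimeError("could not sample a motif-free window")


def _plant_window(rng: np.random.Generator, cls: str, length: int, strict: bool) -> str:
    """Upstream window carrying exactly the motifs of the planted class."""
    while True:
        seq = list(
            _clean_window(rng, length) if strict else _random_seq(rng, length)
        )
        if cls in ("late", "early_and_late"):
            # late element within 80 bp of the start codon
            pos = int(rng.integers(length - 80, length - 5))
            d = "AGT"[int(rng.integers(3))]
            seq[pos : pos + 5] = list(d + "TAAG")
        if cls in ("early", "early_and_late"):
            box = "TATA" + "".join("AT"[int(rng.integers(2))] for _ in range(3))
            box_pos = int(rng.integers(0, length // 2 - 10))
            seq[box_pos : box_pos + 7] = list(box)
            cant = "CA" + "ACGT"[int(rng.integers(4))] + "T"
            cant_pos = int(rng.integers(box_pos + 10, length - 60))
            seq[cant_pos : cant_pos + 4] = list(cant)
        out = "".join(seq)
        if not strict:
            return out
        # planting one motif must not fabricate the other class's signal
        from .promoters import classify_promoter_window

        if classify_promoter_window(out) == cls:
            return out


def generate_genome(
    spec: SyntheticSpec, strict: bool = True
) -> tuple[GenomeRecord, ROTTable, GeneOrderAttributes, dict]:
    """Circular genome with planted ROT runs and promoter classes.

    ROT members are laid out as tandem runs with negative spacers
    (overlapping ORFs) on a shared strand; other spacers are positive.
    In ``strict`` mode every upstream window carries exactly the motifs
    of its planted class and nothing else, so classification recovers
    the planted classes with zero errors.  Returns the genome, the ROT
    interval table, the gene-order attribute list (planted promoter
    class + strand) and the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_orfs
    if sum(spec.rot_runs) > n:
        raise ValueError("infeasible packing: more ROT members than ORFs")
    ids = _gene_ids(n)

    classes = list(spec.promoter_proportions)
    probs = np.array([spec.promoter_proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    planted_class = {
        orf: classes[k] for orf, k in zip(ids, rng.choice(len(classes), n, p=probs))
    }

    # assign ROT runs to non-adjacent stretches of consecutive ORFs
    in_rot: dict[str, str] = {}  # orf -> rot id
    rot_spans: list[list[int]] = []
    cursor = 0
    gaps = max(1, (n - sum(spec.rot_runs)) // (len(spec.rot_runs) + 1))
    for r, run in enumerate(spec.rot_runs, start=1):
        cursor += gaps
        if cursor + run > n:
            raise ValueError("infeasible packing: ROT runs do not fit")
        span = list(range(cursor, cursor + run))
        rot_spans.append(span)
        for k in span:
            in_rot[ids[k]] = f"ROT{r}"
        cursor += run

    # strand per ORF: one strand per ROT run, plus-strand elsewhere so
    # upstream windows never collide in strict mode
    strand = {orf: "+" for orf in ids}
    for span in rot_spans:
        s = "+" if rng.random() < 0.7 else "-"
        for k in span:
            strand[ids[k]] = s

    lengths = rng.integers(*spec.orf_length_range, size=n)
    coords: list[tuple[str, int, int, str]] = []
    pos = 250  # leading pad keeps the first window off the wrap
    prev_strand = None
    for k, orf in enumerate(ids):
        if k == 0:
            start = pos
        else:
            same_rot = in_rot.get(ids[k - 1]) is not None and in_rot.get(
                ids[k - 1]
            ) == in_rot.get(orf)
            if same_rot:
                spacer = int(rng.integers(-25, -3))
            elif prev_strand == "-" and strand[orf] == "+":
                spacer = int(rng.integers(420, 600))  # keep windows disjoint
            else:
                spacer = int(rng.integers(30, 150))
            start = coords[-1][2] + spacer + 1
        end = start + int(lengths[k]) - 1
        coords.append((orf, start, end, strand[orf]))
        prev_strand = strand[orf]
    L = coords[-1][2] + 700  # trailing pad across the origin

    genome_arr = list(_random_seq(rng, L))
    window = 200
    for orf, start, end, s in coords:
        content = _plant_window(rng, planted_class[orf], window, strict)
        if s == "+":
            lo = start - 1 - window
            genome_arr[lo : lo + window] = list(content)
        else:
            genome_arr[end : end + window] = list(_revcomp(content))
    genome = GenomeRecord(sequence="".join(genome_arr), orfs=coords, name="synthetic")

    rots = ROTTable(
        rots=[
            {
                "rot_id": f"ROT{r}",
                "members": [ids[k] for k in span],
                "start": coords[span[0]][1],
                "end": coords[span[-1]][2],
                "orientation": strand[ids[span[0]]],
            }
            for r, span in enumerate(rot_spans, start=1)
        ]
    )
    attrs = GeneOrderAttributes(
        orf_ids=ids,
        values=[planted_class[o] for o in ids],
        strands=[strand[o] for o in ids],
        domain="promoter_class",
    )
    truth = {
        "planted_class": planted_class,
        "in_rot": in_rot,
        "strand": strand,
    }
    return genome, rots, attrs, truth


# -- alignments -----------------------------------------------------------

#: Fixed rooted 4-taxon tree: branch weights sum to 1, so a gene's
#: mutation density d is the expected substitutions per site over the tree.
TREE_BRANCHES = (
    ("root", "AB", 0.1),
    ("AB", "A", 0.2),
    ("AB", "B", 0.2),
    ("root", "CD", 0.1),
    ("CD", "C", 0.2),
    ("CD", "D", 0.2),
)


def expected_segregating_fraction(density: float) -> float:
    """Closed-form expected fraction of segregating columns.

    Any single mutation on any branch makes a column segregating (every
    branch separates the four leaves); the infinite-sites approximation
    ignores repeat hits, so P(segregating) ~= 1 - prod_b (1 - d * w_b).
    """
    p = 1.0
    for _, _, w in TREE_BRANCHES:
        p *= 1.0 - density * w
    return 1.0 - p


def generate_alignments(
    spec: SyntheticSpec, densities: dict[str, float] | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene 4-taxon alignments with planted mutation densities.

    Returns ``{gene_id: [(taxon, sequence), ...]}`` with taxa A-D.  Each
    branch of the fixed tree mutates each site independently with
    probability ``density * branch_weight``; a mutated base changes to
    one of the other three uniformly.
    """
    rng = np.random.default_rng(spec.seed + 3)
    if densities is None:
        genes = _gene_ids(spec.n_alignment_genes)
        densities = {g: spec.mutation_density for g in genes}
    L = spec.alignment_length
    out: dict[str, list[tuple[str, str]]] = {}
    for gene, d in densities.items():
        root = rng.integers(0, 4, size=L)
        node_seq = {"root": root}
        for parent, child, w in TREE_BRANCHES:
            seq = node_seq[parent].copy()
            hit = rng.random(L) < d * w
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            node_seq[child] = seq
        out[gene] = [
            (taxon, "".join(_BASES[node_seq[taxon]])) for taxon in "ABCD"
        ]
    return out


def write_alignments_fasta(alignments: dict, out_dir) -> None:
    """One FASTA per gene under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gene, rows in alignments.items():
        with open(out / f"{gene}.fasta", "w") as fh:
            for taxon, seq in rows:
                fh.write(f">{taxon}\n{seq}\n")
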