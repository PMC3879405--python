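"""End-to-end pipeline orchestration.

One entry point, :func:`run_pipeline`, chains the stages —
load/simulate -> infer -> build -> topology -> communities -> enrichment,
plus optional promoter, spatial and diversity stages — per a config
mapping, writing every intermediate artifact, a provenance record
(versions, seeds, parameters) and a summary JSON into a run directory.
Any stage failure aborts with the stage name and cause; partial outputs
are retained for inspection.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .communities import detect_communities, enrichment_chisq, null_Q_distribution
from .diversity import core_satellite_compare, estimates_to_frame, watterson_theta_from_fasta
from .expression import concatenate_replicates, read_expression_table, write_expression_table
from .grn import rank_edges
from .netbuild import assemble_single_component, hub_scores, prune_network
from .promoters import classify_promoters, read_genome_fasta_gff3, read_genome_genbank, write_promoter_report
from .spatial import GeneOrderAttributes, ROTTable, intergenic_spacers, mc_cooccurrence, rot_membership
from .topology import degree_profiles

logger = logging.getLogger("baculonet")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

_DEFAULTS = {
    "cell_line": "",
    "trees": 1000,
    "feature_subset_rule": "sqrt",
    "ratio": 5.0,
    "window": 200,
    "null_reps": 0,
    "epsilon": 1.7,
    "log_level": "INFO",
    "runs": [],  # e.g. ["late:3", "early:2"]
    "mc_iterations": 100_000,
    "n_genes": 150,  # simulate mode only
    "n_modules": 5,
}


@dataclass
class PipelineConfig:
    """Stage toggles, parameters and paths for one pipeline run.

    ``seed`` is mandatory unless ``allow_unseeded`` is set: every
    stochastic stage is seeded from it, making runs byte-reproducible.
    """

    out_dir: str
    seed: int | None = None
    allow_unseeded: bool = False
    expr: str | None = None  # expression TSV (or None when simulating)
    simulate: bool = False
    genome_fasta: str | None = None
    genome_gff3: str | None = None
    genome_genbank: str | None = None
    rots: str | None = None
    attrs: str | None = None  # node attribute TSV (orf_id + columns)
    aln_dir: str | None = None
    core_labels: str | None = None  # TSV orf_id, core_flag
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None and not self.allow_unseeded:
            raise ValueError(
                "no seed given; pass seed=... or set allow_unseeded"
            )
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged
        for key in ("expr", "genome_fasta", "genome_gff3", "genome_genbank",
                    "rots", "attrs", "aln_dir", "core_labels"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        params = raw.pop("params", {})
        return cls(params=params, **raw)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.params["log_level"])
    p = config.params
    seed = config.seed if config.seed is not None else 0
    summary: dict = {"seed": config.seed}

    series = _load_stage(config, out, seed)
    summary["n_genes"] = series.n_genes
    summary["n_samples"] = series.n_samples

    ranked = _infer_stage(series, p, seed, out)
    net, pruned, edges_used = _build_stage(ranked, series, p, out)
    summary["edges_used"] = edges_used
    summary["pruned_edges"] = pruned.n_edges

    report = _topology_stage(pruned, out)
    summary["acc_slope"] = report.acc_slope
    summary["anc_slope"] = report.anc_slope

    part = _communities_stage(pruned, out)
    summary["n_communities"] = part.n_communities
    summary["modularity_q"] = part.q
    summary["within_edges"] = part.within_edges

    if p["null_reps"] >= 3:
        null = _null_stage(series, p, seed)
        summary["null_q"] = {
            "mean": null["mean_q"],
            "upper99_normal": null["upper99_normal"],
            "upper99_percentile": null["upper99_percentile"],
            "n_reps": null["n_reps"],
        }

    attrs_df = None
    if config.attrs:
        attrs_df = _enrichment_stage(config.attrs, part, out)

    genome = None
    if config.genome_genbank or (config.genome_fasta and config.genome_gff3):
        genome, tally = _promoters_stage(config, p, out)
        summary["promoter_tally"] = tally

    if genome is not None:
        summary["spatial"] = _spatial_stage(config, genome, attrs_df, p, seed, out)

    if config.aln_dir:
        summary["diversity"] = _diversity_stage(config, report, out)

    _write_provenance(config, out)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


@_stage("load")
def _load_stage(config, out, seed):
    if config.simulate:
        from .synthetic import SyntheticSpec, generate_grn, simulate_expression

        spec = SyntheticSpec(
            seed=seed,
            n_genes=int(config.params["n_genes"]),
            n_modules=int(config.params["n_modules"]),
        )
        truth = generate_grn(spec)
        series = concatenate_replicates(*simulate_expression(truth, spec))
        truth.network.write_tsv(out / "truth_network.tsv")
    elif config.expr:
        series = read_expression_table(config.expr, cell_line=config.params["cell_line"])
        with open(out / "load_report.json", "w") as fh:
            json.dump(series.load_report, fh, indent=2, sort_keys=True)
    else:
        raise ValueError("config needs either expr or simulate")
    write_expression_table(series, out / "expression.tsv")
    return series


@_stage("infer")
def _infer_stage(series, p, seed, out):
    ranked = rank_edges(
        series,
        n_trees=int(p["trees"]),
        feature_subset_rule=p["feature_subset_rule"],
        seed=seed,
    )
    ranked.write_tsv(out / "ranked_edges.tsv")
    ranked.write_sif(out / "ranked_edges.sif")
    return ranked


@_stage("build")
def _build_stage(ranked, series, p, out):
    net, edges_used = assemble_single_component(ranked, series.gene_ids)
    net.write_tsv(out / "network_full.tsv")
    hubs = hub_scores(net, epsilon=float(p["epsilon"]))
    pruned = prune_network(net, hubs, target_ratio=float(p["ratio"]))
    pruned.write_tsv(out / "network_pruned.tsv")
    pruned.write_graphml(out / "network_pruned.graphml")
    return net, pruned, edges_used


@_stage("topology")
def _topology_stage(pruned, out):
    report = degree_profiles(pruned)
    report.node_frame().to_csv(out / "topology_nodes.tsv", sep="\t")
    report.degree_frame().to_csv(out / "topology_degree.tsv", sep="\t")
    return report


@_stage("communities")
def _communities_stage(pruned, out):
    part = detect_communities(pruned)
    part.write_tsv(out / "partition.tsv")
    return part


@_stage("null")
def _null_stage(series, p, seed):
    return null_Q_distribution(
        series,
        n_reps=int(p["null_reps"]),
        seed=seed + 7919,
        n_trees=int(p["trees"]),
        target_ratio=float(p["ratio"]),
    )


@_stage("enrichment")
def _enrichment_stage(attrs_path, part, out):
    import pandas as pd

    attrs = pd.read_csv(attrs_path, sep="\t", dtype=str).set_index("orf_id")
    rows = []
    total = len(part.labels)
    for column in attrs.columns:
        series = attrs[column].reindex(part.labels.keys()).dropna()
        for comm in sorted(set(part.labels.values())):
            members = set(part.members(comm))
            for value in sorted(series.unique()):
                carriers = set(series[series == value].index)
                res = enrichment_chisq(
                    in_comm_with_attr=len(members & carriers),
                    total_with_attr=len(carriers),
                    comm_size=len(members),
                    total_nodes=total,
                    community=comm,
                    attribute=f"{column}={value}",
                )
                rows.append(
                    {
                        "community": comm,
                        "attribute": res.attribute,
                        "a": res.table[0], "b": res.table[1],
                        "c": res.table[2], "d": res.table[3],
                        "chi2": res.chi2, "p": res.p,
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    return attrs


@_stage("promoters")
def _promoters_stage(config, p, out):
    if config.genome_genbank:
        genome = read_genome_genbank(config.genome_genbank)
    else:
        genome = read_genome_fasta_gff3(config.genome_fasta, config.genome_gff3)
    _, tally = classify_promoters(genome, window=int(p["window"]))
    write_promoter_report(genome, out / "promoters.tsv", window=int(p["window"]))
    return genome, tally


@_stage("spatial")
def _spatial_stage(config, genome, attrs_df, p, seed, out):
    import pandas as pd

    result: dict = {}
    spacers = intergenic_spacers(genome)
    pd.DataFrame(
        [
            {"orf_a": s["pair"][0], "orf_b": s["pair"][1],
             "spacer_bp": s["spacer_bp"], "overlap": s["overlap"]}
            for s in spacers
        ]
    ).to_csv(out / "spacers.tsv", sep="\t", index=False)
    result["n_overlapping_pairs"] = sum(s["overlap"] for s in spacers)

    if config.rots:
        rots = ROTTable.read_tsv(config.rots)
        _, counts = rot_membership(rots, genome)
        result["rot"] = counts

    if attrs_df is not None and p["runs"]:
        column = attrs_df.columns[0]
        attr_map = attrs_df[column].to_dict()
        order = GeneOrderAttributes.from_genome(genome, attr_map, domain=column)
        result["cooccurrence"] = []
        for spec_str in p["runs"]:
            value, k = spec_str.rsplit(":", 1)
            result["cooccurrence"].append(
                mc_cooccurrence(
                    order, value, int(k),
                    n_iter=int(p["mc_iterations"]), seed=seed + 104729,
                )
            )
    return result


@_stage("diversity")
def _diversity_stage(config, report, out):
    import pandas as pd

    flags = {}
    if config.core_labels:
        lab = pd.read_csv(config.core_labels, sep="\t", dtype=str)
        flags = dict(zip(lab["orf_id"], lab["core_flag"]))
    estimates = []
    for path in sorted(Path(config.aln_dir).glob("*.fasta")):
        gene = path.stem
        estimates.append(
            watterson_theta_from_fasta(
                path, gene_id=gene, core_flag=flags.get(gene, "")
            )
        )
    estimates_to_frame(estimates).to_csv(
        out / "diversity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    shared = [e for e in estimates if e.core_flag and e.gene_id in report.bc]
    if sum(e.core_flag == "core" for e in shared) >= 2 and sum(
        e.core_flag == "satellite" for e in shared
    ) >= 2:
        return core_satellite_compare(shared, report.bc)
    return {"n_estimates": len(estimates)}


def _write_provenance(config: PipelineConfig, out: Path) -> None:
    import networkx
    import numpy
    import scipy
    import sklearn

    prov = {
        "baculonet": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "networkx": networkx.__version__,
        "seed": config.seed,
        "params": config.params,
        "inputs": {
            k: getattr(config, k)
            for k in ("expr", "simulate", "genome_fasta", "genome_gff3",
                      "genome_genbank", "rots", "attrs", "aln_dir")
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
        fh.write("\n")
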