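#!/usr/bin/env python
"""Generate the full synthetic input set with ground truth.

Writes, under results/simulated/: the 150-gene x 30-sample log10
expression table (three concatenated 48-h infection replicates), the
planted regulatory network, a circular genome with planted promoter
motifs and tandem-overlap (ROT) runs, per-gene 4-taxon alignments, and
the ground-truth labels for every planted feature.
"""

import json
from pathlib import Path

from baculonet.expression import concatenate_replicates, write_expression_table
from baculonet.synthetic import (
    SyntheticSpec,
    generate_alignments,
    generate_genome,
    generate_grn,
    simulate_expression,
    write_alignments_fasta,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20130904  # publication date of the study this pipeline mirrors


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(seed=SEED)
    truth = generate_grn(spec)
    series = concatenate_replicates(*simulate_expression(truth, spec))
    write_expression_table(series, OUT / "expression.tsv")
    truth.network.write_tsv(OUT / "truth_network.tsv")

    genome, rots, attrs, planted = generate_genome(spec)
    (OUT / "genome.fasta").write_text(f">{genome.name}\n{genome.sequence}\n")
    with open(OUT / "genome.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for orf, start, end, strand in genome.orfs:
            fh.write(
                f"{genome.name}\tsimulated\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={orf}\n"
            )
    rots.write_tsv(OUT / "rots.tsv")
    with open(OUT / "attributes.tsv", "w") as fh:
        fh.write("orf_id\tpromoter_class\n")
        for orf, value in zip(attrs.orf_ids, attrs.values):
            fh.write(f"{orf}\t{value}\n")
    write_alignments_fasta(generate_alignments(spec), OUT / "alignments")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "seed": SEED,
                "module_of": truth.module_of,
                "planted_promoter_class": planted["planted_class"],
                "in_rot": planted["in_rot"],
            },
            fh, indent=2, sort_keys=True,
        )
    print(f"expression: {series.n_genes} genes x {series.n_samples} samples")
    print(f"planted network: {truth.network.n_edges} edges, "
          f"{len(set(truth.module_of.values()))} modules")
    print(f"genome: {genome.length} bp, {len(genome.orfs)} ORFs, "
          f"{len(rots.rots)} ROT runs")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
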