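"""Study-design constants for the AgMNPV-2D transcriptome analysis.

The AgMNPV-2D genome (accession DQ813662, 132,239 bp) encodes 152
predicted ORFs.  Two of them (ORFs 64 and 83) were not expressed in
either host cell line and ORF 135 was dropped for nonspecific
amplification, leaving 149 ORFs in the network analysis.

The enrichment marginals below are the published community x attribute
counts (attribute carriers inside a community, total carriers, community
size) against the 149-node total; they are inputs to the 2x2 chi-square
recomputation, not precomputed results.
"""

from __future__ import annotations

GENOME_ACCESSION = "DQ813662"
GENOME_LENGTH_BP = 132_239

N_PREDICTED_ORFS = 152

#: ORF number -> reason it was excluded from the network.
EXCLUDED_ORFS = {
    64: "not expressed in either cell line",
    83: "not expressed in either cell line",
    135: "nonspecific amplification",
}

#: Sampling grid, hours post infection.
TIME_GRID_HOURS = (0, 1, 3, 5, 7, 9, 11, 13, 24, 48)

N_REPLICATES = 3

CELL_LINES = ("UFL-AG-286", "IPLB-SF-9")


def analyzed_orf_count() -> int:
    """Number of ORFs entering the network: predicted minus excluded."""
    return N_PREDICTED_ORFS - len(EXCLUDED_ORFS)


def analyzed_orf_numbers() -> list[int]:
    """The ORF numbers retained for network inference."""
    return [
        k for k in range(1, N_PREDICTED_ORFS + 1) if k not in EXCLUDED_ORFS
    ]


#: Published community-enrichment marginals (UFL-AG-286 network):
#: in_comm_with_attr, total_with_attr, comm_size, over the 149-node total.
ENRICHMENT_MARGINALS = [
    {
        "community": "I",
        "attribute": "structural function",
        "in_comm_with_attr": 23,
        "total_with_attr": 36,
        "comm_size": 56,
    },
    {
        "community": "II",
        "attribute": "DNA replication function",
        "in_comm_with_attr": 7,
        "total_with_attr": 12,
        "comm_size": 45,
    },
    {
        "community": "II",
        "attribute": "auxiliary function",
        "in_comm_with_attr": 13,
        "total_with_attr": 30,
        "comm_size": 45,
    },
    {
        "community": "II",
        "attribute": "unknown promoter motif",
        "in_comm_with_attr": 15,
        "total_with_attr": 34,
        "comm_size": 45,
    },
]

#: Published promoter-class tallies over the 149 analyzed ORFs.
PROMOTER_TALLY = {"late": 50, "early": 23, "early_and_late": 42, "none": 34}

#: Published count of ORFs inside regions of overlapping transcription.
N_ORFS_IN_ROTS = 61
N_ROTS = 22
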