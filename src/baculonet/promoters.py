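"""Promoter-motif scanning on circular baculovirus genomes.

Baculovirus transcription uses two promoter systems: early genes are read
by host RNA polymerase II from a TATA box (TATA, or the extended TATAWWW
with W in {A,T}) followed downstream by a CANT motif, while late and very
late genes are read by the viral RNA polymerase from the conserved DTAAG
element (D in {A,G,T}).  Both are searched on the gene's sense strand in
the window immediately 5' of the annotated start codon (200 bp by
default), and each ORF is classified as early, late, early_and_late or
none.

Coordinates follow the GenBank convention: 1-based, inclusive, with
``start < end`` on the plus-strand representation; the genome is circular,
so upstream windows wrap across the origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "PROMOTER_CLASSES",
    "read_genome_fasta_gff3",
    "read_genome_genbank",
    "upstream_region",
    "find_late_motifs",
    "find_early_motifs",
    "classify_promoters",
]

#: Exhaustive, mutually exclusive promoter classes.
PROMOTER_CLASSES = ("early", "late", "early_and_late", "none")

LATE_MOTIF_RE = re.compile(r"(?=([AGT]TAAG))")
TATA_RE = re.compile(r"(?=(TATA[AT]{3}|TATA))")
# ambiguous genome N may sit only at the N position of CANT
CANT_RE = re.compile(r"(?=(CA[ACGTN]T))")


@dataclass
class GenomeRecord:
    """Circular DNA genome with ORF coordinates and strands."""

    sequence: str
    orfs: list[tuple[str, int, int, str]]  # (orf_id, start, end, strand)
    name: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases in genome: {sorted(bad)}")
        L = len(self.sequence)
        seen = set()
        for orf_id, start, end, strand in self.orfs:
            if orf_id in seen:
                raise ValueError(f"duplicate orf id {orf_id!r}")
            seen.add(orf_id)
            if not (1 <= start <= L and 1 <= end <= L):
                raise ValueError(f"orf {orf_id!r} coordinates outside [1, {L}]")
            if start >= end:
                raise ValueError(f"orf {orf_id!r} needs start < end")
            if strand not in "+-":
                raise ValueError(f"orf {orf_id!r} strand must be + or -")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def orf_ids(self) -> list[str]:
        return [o[0] for o in self.orfs]

    def orf(self, orf_id: str) -> tuple[str, int, int, str]:
        for o in self.orfs:
            if o[0] == orf_id:
                return o
        raise KeyError(f"unknown orf {orf_id!r}")

    def orfs_in_genome_order(self) -> list[tuple[str, int, int, str]]:
        return sorted(self.orfs, key=lambda o: (o[1], o[2], o[0]))


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for pair in attr.strip().split(";"):
        if "=" in pair:
            k, v = pair.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genome_fasta_gff3(fasta_path, gff3_path) -> GenomeRecord:
    """Load a circular genome from FASTA plus GFF3 CDS features.

    ORF ids come from the feature's ``ID`` (or ``Name``) attribute.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    rows = pd.read_csv(
        gff3_path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    cds = rows[rows["type"] == "CDS"]
    orfs = []
    for _, row in cds.iterrows():
        attrs = _parse_gff3_attributes(str(row["attributes"]))
        orf_id = attrs.get("ID") or attrs.get("Name")
        if not orf_id:
            raise ValueError(f"CDS feature without ID/Name at {row['start']}")
        orfs.append((orf_id, int(row["start"]), int(row["end"]), str(row["strand"])))
    return GenomeRecord(sequence=str(record.seq), orfs=orfs, name=record.id)


def read_genome_genbank(path) -> GenomeRecord:
    """Load a circular genome from a GenBank flatfile's CDS features.

    ORF ids come from locus_tag, then gene, then a positional fallback.
    """
    record = next(SeqIO.parse(str(path), "genbank"))
    orfs = []
    k = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        k += 1
        quals = feat.qualifiers
        orf_id = (quals.get("locus_tag") or quals.get("gene") or [f"CDS_{k}"])[0]
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "+" if feat.location.strand != -1 else "-"
        orfs.append((orf_id, start, end, strand))
    return GenomeRecord(sequence=str(record.seq), orfs=orfs, name=record.id)


def _circular_slice(seq: str, start0: int, length: int) -> str:
    """``length`` bases starting at 0-based ``start0``, wrapping around."""
    L = len(seq)
    start0 %= L
    if start0 + length <= L:
        return seq[start0 : start0 + length]
    head = seq[start0:]
    need = length - len(head)
    return head + (seq * (need // L + 1))[:need]


def upstream_region(genome: GenomeRecord, orf_id: str, length: int = 200) -> str:
    """Sense-strand upstream window of an ORF, 5'->3' relative to the gene.

    Plus strand: the ``length`` bases immediately 5' of the start
    coordinate (wrapping across the origin).  Minus strand: the reverse
    complement of the ``length`` bases immediately 3' of the end
    coordinate.
    """
    _, start, end, strand = genome.orf(orf_id)
    if length > genome.length:
        raise ValueError(f"window {length} exceeds genome length {genome.length}")
    if strand == "+":
        return _circular_slice(genome.sequence, start - 1 - length, length)
    window = _circular_slice(genome.sequence, end, length)
    return str(Seq(window).reverse_complement())


def find_late_motifs(seq: str) -> list[int]:
    """1-based start positions of DTAAG (D in {A,G,T}); overlaps allowed."""
    return [m.start() + 1 for m in LATE_MOTIF_RE.finditer(seq.upper())]


def find_early_motifs(
    seq: str, max_spacing: int | None = None
) -> list[tuple[int, int]]:
    """(tata_pos, cant_pos) pairs: a TATA/TATAWWW box with CANT downstream.

    Positions are 1-based starts.  The CANT must begin strictly after the
    box ends; ``max_spacing`` optionally bounds the gap between box end
    and CANT start (None = anywhere downstream within the window).
    A classification hit requires at least one pair.
    """
    s = seq.upper()
    pairs = []
    for m in TATA_RE.finditer(s):
        box = m.group(1)
        box_start = m.start() + 1
        box_end = box_start + len(box) - 1
        for c in CANT_RE.finditer(s):
            cant_start = c.start() + 1
            if cant_start <= box_end:
                continue
            if max_spacing is not None and cant_start - box_end - 1 > max_spacing:
                continue
            pairs.append((box_start, cant_start))
    return sorted(set(pairs))


def classify_promoter_window(seq: str, max_spacing: int | None = None) -> str:
    late = bool(find_late_motifs(seq))
    early = bool(find_early_motifs(seq, max_spacing=max_spacing))
    if late and early:
        return "early_and_late"
    if late:
        return "late"
    if early:
        return "early"
    return "none"


def classify_promoters(
    genome: GenomeRecord,
    orf_ids: list[str] | None = None,
    window: int = 200,
    max_spacing: int | None = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify each ORF's upstream window; returns (classes, tally).

    The tally maps each promoter class to the number of ORFs assigned to
    it; tallies always sum to the number of classified ORFs.
    """
    if orf_ids is None:
        orf_ids = genome.orf_ids
    classes = {
        orf: classify_promoter_window(
            upstream_region(genome, orf, window), max_spacing=max_spacing
        )
        for orf in orf_ids
    }
    tally = Counter(classes.values())
    return classes, {cls: tally.get(cls, 0) for cls in PROMOTER_CLASSES}


def write_promoter_report(
    genome: GenomeRecord, path, orf_ids: list[str] | None = None, window: int = 200
) -> None:
    """TSV report: orf_id, class, late positions, early (tata, cant) pairs."""
    if orf_ids is None:
        orf_ids = genome.orf_ids
    rows = []
    for orf in orf_ids:
        seq = upstream_region(genome, orf, window)
        late = find_late_motifs(seq)
        early = find_early_motifs(seq)
        rows.append(
            {
                "orf_id": orf,
                "class": classify_promoter_window(seq),
                "late_positions": ",".join(map(str, late)),
                "early_pairs": ";".join(f"{t},{c}" for t, c in early),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
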