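"""Genome-architecture statistics on the circular gene order.

Covers four analyses: intergenic spacer lengths between consecutive ORFs
(negative spacer = overlapping genes); membership of ORFs in regions of
overlapping transcription (ROTs — loci producing tandem transcripts of
different lengths); a Monte Carlo runs test for whether a categorical gene
attribute (community, promoter class, functional category) clusters in
tandem along the genome more than a random arrangement would allow; and a
Mantel-style comparison of expression-profile distance with physical
map-unit distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import EnrichmentResult, enrichment_chisq
from .expression import ExpressionSeries
from .promoters import GenomeRecord

__all__ = [
    "ROTTable",
    "GeneOrderAttributes",
    "intergenic_spacers",
    "rot_membership",
    "mc_cooccurrence",
    "expression_vs_position",
    "circular_map_distance",
]


@dataclass
class ROTTable:
    """Regions of overlapping transcription: id, member ORFs, interval."""

    rots: list[dict]  # keys: rot_id, members, start, end, orientation

    def __post_init__(self) -> None:
        for rot in self.rots:
            rot["members"] = [str(m) for m in rot["members"]]

    @property
    def all_members(self) -> set[str]:
        out: set[str] = set()
        for rot in self.rots:
            out.update(rot["members"])
        return out

    @classmethod
    def read_tsv(cls, path) -> "ROTTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        rots = []
        for _, row in df.iterrows():
            rots.append(
                {
                    "rot_id": row["rot_id"],
                    "members": [m for m in str(row["members"]).split(",") if m],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "orientation": row.get("orientation", "+"),
                }
            )
        return cls(rots=rots)

    def write_tsv(self, path) -> None:
        rows = [
            {
                "rot_id": r["rot_id"],
                "members": ",".join(r["members"]),
                "start": r["start"],
                "end": r["end"],
                "orientation": r.get("orientation", "+"),
            }
            for r in self.rots
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GeneOrderAttributes:
    """Circular ordered (orf_id, attribute, strand) list for one domain."""

    orf_ids: list[str]
    values: list[str]
    strands: list[str]
    domain: str = ""

    def __post_init__(self) -> None:
        if not (len(self.orf_ids) == len(self.values) == len(self.strands)):
            raise ValueError("orf_ids, values and strands must be equal length")

    @classmethod
    def from_genome(
        cls, genome: GenomeRecord, attribute: dict[str, str], domain: str = ""
    ) -> "GeneOrderAttributes":
        orfs = genome.orfs_in_genome_order()
        return cls(
            orf_ids=[o[0] for o in orfs],
            values=[str(attribute[o[0]]) for o in orfs],
            strands=[o[3] for o in orfs],
            domain=domain,
        )


def intergenic_spacers(
    genome: GenomeRecord, short_threshold: int = 10
) -> list[dict]:
    """Spacer between each pair of consecutive ORFs in circular order.

    spacer = next.start - current.end - 1; negative means the ORFs
    overlap.  The wrap-around pair (last ORF back to the first) is
    included with the spacer measured across the origin.
    """
    orfs = genome.orfs_in_genome_order()
    if len(orfs) < 2:
        raise ValueError("need >= 2 ORFs")
    L = genome.length
    out = []
    for k, cur in enumerate(orfs):
        nxt = orfs[(k + 1) % len(orfs)]
        if k + 1 < len(orfs):
            spacer = nxt[1] - cur[2] - 1
        else:
            spacer = (nxt[1] + L) - cur[2] - 1
        out.append(
            {
                "pair": (cur[0], nxt[0]),
                "spacer_bp": int(spacer),
                "overlap": spacer < 0,
                "very_short": 0 <= spacer <= short_threshold,
            }
        )
    return out


def rot_membership(
    rots: ROTTable, genome: GenomeRecord
) -> tuple[dict[str, bool], dict]:
    """Per-ORF in-ROT flag, counts, and the overlap-vs-ROT chi-square.

    The chi-square asks whether ORFs that overlap a neighbour (negative
    spacer on either side) are over-represented inside ROTs, via the same
    uncorrected Pearson 2x2 used for community enrichment.
    """
    known = set(genome.orf_ids)
    unknown = sorted(rots.all_members - known)
    if unknown:
        raise KeyError(f"ROT members absent from genome: {unknown[:5]}")
    members = rots.all_members
    flags = {orf: orf in members for orf in genome.orf_ids}
    n_in = sum(flags.values())

    overlapping: set[str] = set()
    if len(genome.orfs) >= 2:
        for rec in intergenic_spacers(genome):
            if rec["overlap"]:
                overlapping.update(rec["pair"])
    a = sum(1 for orf in members if orf in overlapping)
    chisq: EnrichmentResult = enrichment_chisq(
        in_comm_with_attr=a,
        total_with_attr=len(overlapping),
        comm_size=n_in,
        total_nodes=len(flags),
        community="in_rot",
        attribute="overlapping",
    )
    counts = {
        "n_orfs": len(flags),
        "n_in_rot": n_in,
        "n_rots": len(rots.rots),
        "n_overlapping": len(overlapping),
        "overlap_vs_rot_chi2": chisq.chi2,
        "overlap_vs_rot_p": chisq.p,
    }
    return flags, counts


def has_cooccurrence_run(
    is_value: np.ndarray,
    run_length: int,
    circular: bool = True,
    strands: np.ndarray | None = None,
) -> np.ndarray:
    """Whether each arrangement contains a tandem run of the value.

    ``is_value`` is a boolean array of shape (n,) or (batch, n); a run is
    ``run_length`` consecutive hits (wrapping across the origin when
    ``circular``).  With ``strands`` given (same shape, entries '+'/'-' or
    +-1), every position of the run must share one strand.  Returns a
    boolean per arrangement.
    """
    arr = np.atleast_2d(np.asarray(is_value, dtype=bool))
    k = run_length
    if k <= 1:
        out = arr.any(axis=1)
        return out if np.asarray(is_value).ndim > 1 else out[0]
    if circular:
        arr_ext = np.concatenate([arr, arr[:, : k - 1]], axis=1)
    else:
        arr_ext = arr
    # window of k consecutive hits <=> windowed sum equals k
    c = np.cumsum(arr_ext.astype(np.int32), axis=1)
    c = np.concatenate([np.zeros((arr.shape[0], 1), dtype=np.int32), c], axis=1)
    win = c[:, k:] - c[:, :-k]
    hit = win == k
    if strands is not None:
        s = np.atleast_2d(np.asarray(strands))
        if s.dtype.kind in "USO":
            sgn = np.where(s == "+", 1, -1).astype(np.int32)
        else:
            sgn = s.astype(np.int32)
        sgn = np.where(arr, sgn, 0)
        if circular:
            sgn = np.concatenate([sgn, sgn[:, : k - 1]], axis=1)
        cs = np.cumsum(sgn, axis=1)
        cs = np.concatenate([np.zeros((arr.shape[0], 1), dtype=np.int32), cs], axis=1)
        swin = cs[:, k:] - cs[:, :-k]
        hit &= np.abs(swin) == k
    out = hit.any(axis=1)
    return out if np.asarray(is_value).ndim > 1 else out[0]


def mc_cooccurrence(
    attrs: GeneOrderAttributes,
    value: str,
    run_length: int,
    strand_restricted: bool = False,
    n_iter: int = 1_000_000,
    seed: int = 0,
    circular: bool = True,
    batch: int = 20_000,
) -> dict:
    """Monte Carlo probability of a tandem run of an attribute value.

    Estimates the probability that a uniform random permutation of the
    attribute list (attributes and strands permuted jointly) contains at
    least one run of ``run_length`` consecutive entries equal to ``value``
    — circular runs by default.  With ``strand_restricted`` the run must
    additionally lie on one strand.  Returns the estimate with its
    binomial standard error; deterministic under a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = np.array(attrs.values)
    strands = np.array(attrs.strands)
    count = int((values == value).sum())
    if count < run_length:
        raise ValueError(
            f"run_length {run_length} exceeds count of {value!r} ({count})"
        )
    rng = np.random.default_rng(seed)
    n = values.size
    is_val = values == value
    hits = 0
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        perm = np.argsort(rng.random((b, n)), axis=1)
        batch_vals = is_val[perm]
        batch_strands = strands[perm] if strand_restricted else None
        hits += int(
            has_cooccurrence_run(
                batch_vals, run_length, circular=circular, strands=batch_strands
            ).sum()
        )
        done += b
    p = hits / n_iter
    se = float(np.sqrt(p * (1 - p) / n_iter))
    return {
        "value": value,
        "run_length": run_length,
        "p": p,
        "se": se,
        "n_iter": n_iter,
        "circular": circular,
        "strand_restricted": strand_restricted,
    }


def circular_map_distance(genome: GenomeRecord) -> pd.DataFrame:
    """Pairwise shorter-arc distance between ORF midpoints, in map units.

    One map unit is 1% of genome length, so distances lie in [0, 50].
    """
    orfs = genome.orfs_in_genome_order()
    L = genome.length
    mids = np.array([(o[1] + o[2]) / 2.0 for o in orfs])
    ids = [o[0] for o in orfs]
    diff = np.abs(mids[:, None] - mids[None, :])
    arc = np.minimum(diff, L - diff)
    return pd.DataFrame(arc / L * 100.0, index=ids, columns=ids)


def expression_vs_position(
    series: ExpressionSeries,
    genome: GenomeRecord,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Do physically close genes have similar expression profiles?

    Computes, over all shared gene pairs, the Euclidean distance between
    mean-over-replicate log10 profiles and the circular map-unit distance,
    then Pearson and Spearman correlations with a Mantel-style permutation
    p (gene labels of the expression matrix permuted; one-sided for
    positive association).  Degenerate inputs (all profiles identical) are
    flagged instead of reporting a correlation.
    """
    shared = [g for g in series.gene_ids if g in set(genome.orf_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 genes shared between series and genome")
    profiles = series.mean_over_replicates().loc[shared].to_numpy()
    # condensed pairwise distances over shared genes
    from scipy.spatial.distance import pdist, squareform

    expr_d = squareform(pdist(profiles))
    map_d = circular_map_distance(genome).loc[shared, shared].to_numpy()
    iu = np.triu_indices(len(shared), k=1)
    ev, mv = expr_d[iu], map_d[iu]
    if np.allclose(ev, 0.0):
        return {"degenerate": True, "reason": "all expression profiles identical"}

    r_obs = float(stats.pearsonr(ev, mv).statistic)
    rho_obs = float(stats.spearmanr(ev, mv).statistic)
    rng = np.random.default_rng(seed)
    n = len(shared)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pv = expr_d[np.ix_(perm, perm)][iu]
        if float(stats.pearsonr(pv, mv).statistic) >= r_obs:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    return {
        "degenerate": False,
        "n_genes": n,
        "pearson_r": r_obs,
        "spearman_rho": rho_obs,
        "mantel_p": float(p_perm),
        "n_perm": n_perm,
    }
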