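"""qPCR expression time series: container, I/O, replicate concatenation, nulls.

The central object is :class:`ExpressionSeries`, a gene x sample matrix of
log10 relative expression with per-column time (hours post infection) and
replicate metadata.  Non-detected samples are stored as a configurable
detection-floor sentinel (0.0 on the log10 scale by default), matching the
convention of deposited baculovirus qPCR tables.

The time-shuffling null (:func:`shuffle_time_points`) permutes each gene's
values across columns, destroying temporal structure while preserving the
per-gene value distribution exactly — the null model used to contrast
inferred networks against randomized ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSeries",
    "DEFAULT_TIME_GRID",
    "read_expression_table",
    "write_expression_table",
    "concatenate_replicates",
    "shuffle_time_points",
]

#: Sampling grid of the infection time course, in hours post infection.
DEFAULT_TIME_GRID = (0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 24.0, 48.0)

_HEADER_RE = re.compile(r"^rep(\d+)_t([0-9]+(?:\.[0-9]+)?)$")


@dataclass
class ExpressionSeries:
    """Gene x sample matrix of log10 relative expression.

    Parameters
    ----------
    gene_ids
        Ordered, unique ORF identifiers (one per matrix row).
    sample_times
        Hours post infection for each column; strictly increasing within
        each replicate block.
    replicate_of
        Replicate index for each column.
    values
        ``(n_genes, n_samples)`` float array, all entries finite.
    cell_line
        Free-text label of the host cell line the series was measured in.
    detection_floor
        Sentinel value that encodes "not detected" samples.
    """

    gene_ids: list[str]
    sample_times: np.ndarray
    replicate_of: np.ndarray
    values: np.ndarray
    cell_line: str = ""
    detection_floor: float = 0.0
    load_report: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.replicate_of = np.asarray(self.replicate_of, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.gene_ids) != len(set(self.gene_ids)):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.sample_times.shape != (n_samples,):
            raise ValueError("sample_times length does not match column count")
        if self.replicate_of.shape != (n_samples,):
            raise ValueError("replicate_of length does not match column count")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, column {j}"
            )
        for rep in np.unique(self.replicate_of):
            t = self.sample_times[self.replicate_of == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times not strictly increasing within replicate {rep}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def replicates(self) -> list[int]:
        return sorted(set(self.replicate_of.tolist()))

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"rep{r}_t{_fmt_time(t)}"
            for r, t in zip(self.replicate_of, self.sample_times)
        ]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)

    def mean_over_replicates(self) -> pd.DataFrame:
        """Per-gene profile averaged over replicates (columns = times)."""
        times = np.unique(self.sample_times)
        out = np.empty((self.n_genes, times.size))
        for k, t in enumerate(times):
            out[:, k] = self.values[:, self.sample_times == t].mean(axis=1)
        return pd.DataFrame(out, index=self.gene_ids, columns=times)

    def subset(self, gene_ids: list[str]) -> "ExpressionSeries":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionSeries(
            gene_ids=list(gene_ids),
            sample_times=self.sample_times.copy(),
            replicate_of=self.replicate_of.copy(),
            values=self.values[rows].copy(),
            cell_line=self.cell_line,
            detection_floor=self.detection_floor,
        )


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def read_expression_table(
    path, cell_line: str = "", detection_floor: float = 0.0
) -> ExpressionSeries:
    """Read an ORF x (replicate, time) expression table.

    The file is TSV or CSV (sniffed from the extension; ``.csv`` means
    comma) with a header row ``orf_id, rep<k>_t<hours>, ...``.  Blank cells
    are imputed with the detection floor and counted in
    ``series.load_report["n_imputed"]``.

    Raises
    ------
    ValueError
        On duplicate gene ids, non-numeric cells or malformed headers,
        with row/column coordinates in the message.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns[0] != "orf_id":
        raise ValueError(f"first column must be 'orf_id', got {df.columns[0]!r}")
    gene_ids = df["orf_id"].tolist()
    dups = [g for g in set(gene_ids) if gene_ids.count(g) > 1]
    if dups:
        raise ValueError(f"duplicate gene ids: {sorted(dups)}")

    times, reps = [], []
    for col in df.columns[1:]:
        m = _HEADER_RE.match(col)
        if not m:
            raise ValueError(f"malformed sample header {col!r} (want rep<k>_t<hours>)")
        reps.append(int(m.group(1)))
        times.append(float(m.group(2)))

    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    n_imputed = 0
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "" or cell.upper() in {"NA", "NAN", "ND"}:
                values[i, j] = detection_floor
                n_imputed += 1
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {gene_ids[i]!r}, "
                    f"column {df.columns[1 + j]!r}"
                ) from None

    series = ExpressionSeries(
        gene_ids=gene_ids,
        sample_times=np.array(times),
        replicate_of=np.array(reps),
        values=values,
        cell_line=cell_line,
        detection_floor=detection_floor,
    )
    series.load_report = {
        "path": str(path),
        "n_genes": series.n_genes,
        "n_samples": series.n_samples,
        "n_imputed": n_imputed,
    }
    return series


def write_expression_table(series: ExpressionSeries, path) -> None:
    """Write a series back to TSV/CSV; round-trips values bit-exactly."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = series.to_frame()
    df.index.name = "orf_id"
    # repr-roundtrip precision so read_expression_table restores bit-exact floats
    df.to_csv(path, sep=sep, float_format="%.17g")


def concatenate_replicates(*series_list: ExpressionSeries) -> ExpressionSeries:
    """Concatenate replicate series into one long series, column-wise.

    All inputs must share the same gene set (rows are aligned by gene id,
    so input row order may differ) and the same within-replicate time grid.
    Replicate indices are re-numbered consecutively so they stay unique
    across the concatenation.  Three 10-point replicates thus become one
    30-column series — the "successive infection cycles" series the network
    inference consumes.
    """
    if not series_list:
        raise ValueError("no series given")
    if len(series_list) == 1 and len(series_list[0].replicates) >= 1:
        s = series_list[0]
        return ExpressionSeries(
            gene_ids=list(s.gene_ids),
            sample_times=s.sample_times.copy(),
            replicate_of=s.replicate_of.copy(),
            values=s.values.copy(),
            cell_line=s.cell_line,
            detection_floor=s.detection_floor,
        )
    ref = series_list[0]
    ref_genes = sorted(ref.gene_ids)
    ref_grid = ref.sample_times[ref.replicate_of == ref.replicates[0]]
    blocks, times, reps = [], [], []
    next_rep = 1
    for s in series_list:
        if sorted(s.gene_ids) != ref_genes:
            raise ValueError("gene id sets differ between series")
        aligned = s.subset(list(ref.gene_ids))
        for rep in aligned.replicates:
            mask = aligned.replicate_of == rep
            grid = aligned.sample_times[mask]
            if grid.shape != ref_grid.shape or not np.allclose(grid, ref_grid):
                raise ValueError(f"time grid mismatch in replicate {rep}")
            blocks.append(aligned.values[:, mask])
            times.append(grid)
            reps.append(np.full(mask.sum(), next_rep))
            next_rep += 1
    return ExpressionSeries(
        gene_ids=list(ref.gene_ids),
        sample_times=np.concatenate(times),
        replicate_of=np.concatenate(reps),
        values=np.concatenate(blocks, axis=1),
        cell_line=ref.cell_line,
        detection_floor=ref.detection_floor,
    )


def shuffle_time_points(
    series: ExpressionSeries, seed: int, mode: str = "per_gene"
) -> ExpressionSeries:
    """Permute values across columns, keeping column metadata fixed.

    ``per_gene`` (default) draws an independent permutation for every gene,
    destroying both temporal structure and gene-gene cross-correlation —
    the null used for randomized-network comparisons.  ``shared`` applies
    one common column permutation to every gene, which scrambles time but
    preserves same-column cross-correlations.
    """
    if mode not in {"per_gene", "shared"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    values = series.values.copy()
    if mode == "shared":
        perm = rng.permutation(series.n_samples)
        values = values[:, perm]
    else:
        for i in range(series.n_genes):
            values[i] = values[i, rng.permutation(series.n_samples)]
    return ExpressionSeries(
        gene_ids=list(series.gene_ids),
        sample_times=series.sample_times.copy(),
        replicate_of=series.replicate_of.copy(),
        values=values,
        cell_line=series.cell_line,
        detection_floor=series.detection_floor,
    )
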