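"""Tree-ensemble gene regulatory network inference.

For every target gene, an ensemble of regression trees predicts the
target's expression across samples from the same-sample expression of all
other genes.  The importance of regulator *i* for target *j* is the total
impurity (variance) reduction attributed to feature *i*, averaged over the
ensemble and normalized so that the incoming importances of each
non-constant target sum to one.  Concatenating all target-wise importances
and sorting yields a confidence-ranked list of directed regulatory edges.

Samples are treated as exchangeable observations: the learner sees no time
axis, so ranking is invariant to sample order.  Ensemble diversity comes
from random per-split feature subsampling (K = ceil(sqrt(G-1)) by default);
bootstrap resampling is deliberately not used, which keeps the weights
exactly invariant under sample permutation.  An optional one-step lag mode
regresses each target at t+1 on regulators at t within each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .expression import ExpressionSeries

__all__ = ["RankedEdgeList", "rank_edges"]


@dataclass
class RankedEdgeList:
    """Directed regulator->target edges ordered by importance weight.

    ``edges`` is a list of ``(regulator_id, target_id, weight)`` sorted by
    non-increasing weight, ties broken lexicographically on
    ``(regulator, target)`` so output is deterministic.
    """

    edges: list[tuple[str, str, float]]
    n_trees: int = 0
    feature_subset_rule: str = "sqrt"
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, tgt, w in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge {reg!r}")
            if w < 0:
                raise ValueError(f"negative weight on {reg}->{tgt}")
        self.edges = sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "weight"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_sif(self, path) -> None:
        """Simple-interaction-format export (regulator  regulates  target)."""
        with open(path, "w") as fh:
            for reg, tgt, _ in self.edges:
                fh.write(f"{reg}\tregulates\t{tgt}\n")

    @classmethod
    def read_tsv(cls, path) -> "RankedEdgeList":
        df = pd.read_csv(path, sep="\t")
        edges = [
            (str(r), str(t), float(w))
            for r, t, w in df[["regulator", "target", "weight"]].itertuples(index=False)
        ]
        return cls(edges=edges)


def _lagged_design(series: ExpressionSeries):
    """Regulators at t, target at t+1, within each replicate block."""
    x_cols, y_cols = [], []
    for rep in series.replicates:
        idx = np.flatnonzero(series.replicate_of == rep)
        x_cols.extend(idx[:-1])
        y_cols.extend(idx[1:])
    return np.array(x_cols), np.array(y_cols)


def rank_edges(
    series: ExpressionSeries,
    n_trees: int = 1000,
    feature_subset_rule: str = "sqrt",
    seed: int = 0,
    lag: int = 0,
) -> RankedEdgeList:
    """Rank all directed gene-gene edges by ensemble importance.

    Parameters
    ----------
    series
        Expression matrix; needs at least 3 genes and 5 samples.
    n_trees
        Trees per target-wise ensemble (method default 1000).
    feature_subset_rule
        ``"sqrt"`` — K = ceil(sqrt(G-1)) candidate regulators per split;
        ``"all"`` — every regulator considered at every split.
    seed
        Seed for the per-target ensembles; fixed seed gives identical
        output.
    lag
        0 (default) regresses same-sample values; 1 regresses each target
        at t+1 on regulators at t within each replicate.

    Returns
    -------
    RankedEdgeList
        All G*(G-1) directed edges with normalized importance weights.
        Targets with zero variance get all-zero incoming weights and a
        warning.
    """
    G = series.n_genes
    if G < 3:
        raise ValueError(f"need >= 3 genes, got {G}")
    values = series.values
    if lag == 0:
        X_all = values.T  # samples x genes
        Y_all = values.T
    elif lag == 1:
        x_cols, y_cols = _lagged_design(series)
        X_all = values[:, x_cols].T
        Y_all = values[:, y_cols].T
    else:
        raise ValueError("lag must be 0 or 1")
    n_samples = X_all.shape[0]
    if n_samples < 5:
        raise ValueError(f"need >= 5 samples, got {n_samples}")

    if feature_subset_rule == "sqrt":
        max_features = int(np.ceil(np.sqrt(G - 1)))
    elif feature_subset_rule == "all":
        max_features = G - 1
    else:
        raise ValueError(f"unknown feature_subset_rule {feature_subset_rule!r}")

    rng = np.random.default_rng(seed)
    target_seeds = rng.integers(0, 2**31 - 1, size=G)

    edges: list[tuple[str, str, float]] = []
    genes = series.gene_ids
    for j in range(G):
        y = Y_all[:, j]
        regulators = [g for g in range(G) if g != j]
        sd = y.std()
        if sd == 0.0:
            warnings.warn(
                f"target {genes[j]!r} has zero variance; incoming weights set to 0",
                stacklevel=2,
            )
            importances = np.zeros(G - 1)
        else:
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                bootstrap=False,
                random_state=int(target_seeds[j]),
                n_jobs=1,
            )
            forest.fit(X_all[:, regulators], y / sd)
            importances = forest.feature_importances_
        for k, i in enumerate(regulators):
            edges.append((genes[i], genes[j], float(importances[k])))

    return RankedEdgeList(
        edges=edges,
        n_trees=n_trees,
        feature_subset_rule=feature_subset_rule,
        seed=seed,
        metadata={"lag": lag, "n_samples": n_samples},
    )
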