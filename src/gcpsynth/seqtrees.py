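"""Sequential decision-tree synthesis of the latent patient table.

For latent columns a_1..a_R (in table order) the method fits R-1 regression
trees, M_j : (a_1, ..., a_{j-1}) -> a_j.  Sampling draws synthetic a_1 by
bootstrap from the observed a_1 column, then for each j routes the partial
synthetic row down M_j and resamples a_j uniformly from the *training*
values that landed in the same terminal node.  Every synthetic value is
therefore a value observed in that column's training data (no smoothing by
default; a Gaussian-kernel jitter can be switched on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .latent import LatentTable

__all__ = ["TreeOptions", "SeqTreeModel", "seqtree_fit", "seqtree_sample"]


@dataclass(frozen=True)
class TreeOptions:
    """Hyperparameters of each per-column regression tree."""

    min_samples_leaf: int = 5
    max_depth: int | None = None
    smoothing: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class SeqTreeModel:
    """R-1 fitted trees plus, per tree, the leaf -> training-values map."""

    columns: list[str]
    first_column_values: np.ndarray
    trees: list[DecisionTreeRegressor]
    leaf_values: list[dict[int, np.ndarray]]
    options: TreeOptions
    template: LatentTable = field(repr=False, default=None)  # type: ignore[assignment]


def seqtree_fit(latent: LatentTable, options: TreeOptions | None = None) -> SeqTreeModel:
    """Fit the sequential chain of regression trees on the latent table."""
    options = options or TreeOptions()
    if latent.n_rows < 2:
        raise ValueError("sequential-tree synthesis needs at least 2 rows")
    x = latent.values()
    cols = latent.columns
    trees: list[DecisionTreeRegressor] = []
    leaf_values: list[dict[int, np.ndarray]] = []
    for j in range(1, len(cols)):
        tree = DecisionTreeRegressor(
            min_samples_leaf=options.min_samples_leaf,
            max_depth=options.max_depth,
            random_state=options.random_seed,
        )
        tree.fit(x[:, :j], x[:, j])
        leaves = tree.apply(x[:, :j])
        lv = {int(leaf): x[leaves == leaf, j] for leaf in np.unique(leaves)}
        trees.append(tree)
        leaf_values.append(lv)
    return SeqTreeModel(cols, x[:, 0].copy(), trees, leaf_values, options, latent)


def seqtree_sample(model: SeqTreeModel, n_out: int, seed: int = 0) -> LatentTable:
    """Draw ``n_out`` synthetic rows from the fitted sequential chain."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    rng = np.random.default_rng(seed)
    R = len(model.columns)
    out = np.empty((n_out, R))
    out[:, 0] = rng.choice(model.first_column_values, size=n_out, replace=True)
    for j in range(1, R):
        tree = model.trees[j - 1]
        lv = model.leaf_values[j - 1]
        leaves = tree.apply(out[:, :j])
        col = np.empty(n_out)
        for leaf in np.unique(leaves):
            idx = np.where(leaves == leaf)[0]
            pool = lv[int(leaf)]
            col[idx] = rng.choice(pool, size=idx.size, replace=True)
            if model.options.smoothing and pool.size > 1:
                # Silverman bandwidth jitter within the leaf
                bw = 1.06 * pool.std(ddof=1) * pool.size ** (-1 / 5)
                col[idx] += rng.normal(0.0, bw, size=idx.size)
        out[:, j] = col
    return model.template.like(out)
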