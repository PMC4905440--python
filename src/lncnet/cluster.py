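"""Hierarchical clustering of expression profiles for the heatmap view.

Distance is 1 - r with r the centered Pearson correlation across samples
(means subtracted, i.e. the ordinary correlation coefficient — correlation
is scale-invariant, so clustering runs on raw log2 values and row
standardization is applied for display only). Linkage defaults to average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ValidationError

LINKAGES = ("single", "complete", "average")


def pearson_distance_matrix(values: pd.DataFrame, centered: bool = True) -> pd.DataFrame:
    """Pairwise d(i,j) = 1 - r(i,j) between rows of ``values``.

    ``centered=False`` uses the uncentered correlation (cosine of the raw
    vectors), the alternative convention of classic clustering tools.
    Zero-variance rows make r undefined and are a hard error listing the
    offending ids.
    """
    X = values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 rows to compute distances")
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    zero = np.asarray(values.index)[norms == 0].tolist()
    if zero:
        raise ValidationError(f"zero-variance probe(s), correlation undefined: {zero}")
    R = (X / norms[:, None]) @ (X / norms[:, None]).T
    D = 1.0 - np.clip(R, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(D, index=values.index, columns=values.index)


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "average"):
    """Agglomerative clustering of a precomputed distance matrix.

    Returns (merge_tree, leaf_order): the SciPy linkage matrix and the ids
    in dendrogram leaf order. Deterministic for a given input (ties resolve
    by input index).
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    n = distances.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 items to cluster")
    condensed = squareform(distances.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = [distances.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def top_level_split(Z, ids) -> tuple[set, set]:
    """The two branches below the root merge, as sets of leaf ids."""
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    a = {i for i, lab in zip(ids, labels) if lab == 1}
    b = {i for i, lab in zip(ids, labels) if lab == 2}
    return a, b


def to_newick(Z, ids) -> str:
    """Render a linkage matrix as a Newick string, branch lengths = height deltas."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def standardize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row mean 0, sd 1 (population sd), for heatmap display."""
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = np.asarray(values.index)[(sd == 0).ravel()].tolist()
        raise ValidationError(f"zero-variance probe(s) cannot be standardized: {bad}")
    return pd.DataFrame((X - mu) / sd, index=values.index, columns=values.columns)


def export_heatmap_table(values: pd.DataFrame, row_order, col_order, path) -> pd.DataFrame:
    """Write the row-standardized matrix in dendrogram order as TSV.

    ``row_order`` / ``col_order`` must be permutations of the matrix ids.
    Returns the written frame. Plotting is left to the caller.
    """
    if sorted(row_order) != sorted(values.index) or sorted(col_order) != sorted(values.columns):
        raise ValidationError("row/col orders must be permutations of the matrix ids")
    out = standardize_rows(values).loc[list(row_order), list(col_order)]
    out.to_csv(path, sep="\t", index_label="probe_id")
    return out
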