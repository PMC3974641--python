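"""Ward clustering of protein-drug coefficient profiles.

Proteins are clustered by their standardized regression coefficients across
the four drug phenotypes (drug x {apoptosis, cytotoxicity}), with apoptosis
coefficients sign-inverted so all columns share the cytotoxicity direction
convention.  The number of significant clusters is chosen by permutation:
each column of the coefficient matrix is shuffled independently across rows
(destroying row structure, preserving column marginals), the permuted
matrix is clustered, and its maximum merge height recorded; the observed
dendrogram is cut at the lowest observed merge height that exceeds the
permutation max-height envelope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "CoefficientMatrix",
    "ClusterSolution",
    "build_coefficient_matrix",
    "ward_cluster",
    "permutation_k",
    "dendrogram_newick",
]


@dataclass
class CoefficientMatrix:
    """Antibody x phenotype standardized coefficients, apoptosis sign-flipped.

    ``sign_convention`` records which columns were inverted on build.
    """

    values: pd.DataFrame
    sign_convention: dict

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("coefficient matrix must be finite")


@dataclass
class ClusterSolution:
    linkage: np.ndarray  # scipy linkage matrix
    merge_heights: np.ndarray
    k: int
    assignments: pd.Series
    perm_max_heights: np.ndarray
    p: float
    cut_height: float


def build_coefficient_matrix(assoc: pd.DataFrame, phenotypes: list[str] | None = None) -> CoefficientMatrix:
    """Pivot association results to an antibody x phenotype coefficient matrix.

    Rows with any missing coefficient are dropped (logged via warning);
    apoptosis columns are multiplied by -1; every column is then z-scored.
    Zero-variance columns cannot be standardized and are dropped.
    """
    mat = assoc.pivot_table(index="antibody", columns="phenotype", values="beta", aggfunc="first")
    if phenotypes is not None:
        mat = mat[phenotypes]
    n0 = len(mat)
    mat = mat.dropna()
    if len(mat) < n0:
        warnings.warn(f"dropped {n0 - len(mat)} antibodies with incomplete coefficients")
    if len(mat) < 2:
        raise ValueError("need >= 2 complete antibody rows")
    convention = {}
    for col in mat.columns:
        inverted = "apoptosis" in str(col)
        convention[col] = -1 if inverted else 1
        if inverted:
            mat[col] = -mat[col]
    sd = mat.std(ddof=0)
    dead = sd[np.isclose(sd, 0.0, atol=1e-10)].index
    if len(dead):
        warnings.warn(f"dropping zero-variance columns: {list(dead)}")
        mat = mat.drop(columns=dead)
    mat = (mat - mat.mean()) / mat.std(ddof=0)
    return CoefficientMatrix(values=mat, sign_convention=convention)


def ward_cluster(matrix: CoefficientMatrix | pd.DataFrame) -> np.ndarray:
    """Agglomerative Ward linkage (Ward.D2 on Euclidean distances)."""
    vals = matrix.values if isinstance(matrix, CoefficientMatrix) else matrix
    arr = np.asarray(vals, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 rows to cluster")
    if not np.isfinite(arr).all():
        raise ValueError("NaN/inf in coefficient matrix")
    return hierarchy.linkage(arr, method="ward")


def permutation_k(
    matrix: CoefficientMatrix | pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "max_height",
) -> ClusterSolution:
    """Permutation test for the number of significant clusters.

    For each permutation the columns are shuffled independently across rows
    and the Ward dendrogram's maximum merge height recorded.  The observed
    tree is cut just below the smallest observed merge height exceeding the
    maximum over all permutation heights; k is the cluster count at that
    cut and p = (1 + #{perm max >= cut height}) / (1 + n_perm).  With no
    observed height above the envelope there is no significant structure
    (k = 1, p = 1).  ``mode='per_merge'`` instead compares each merge
    height with the permutation distribution of the same merge index.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vals = matrix.values if isinstance(matrix, CoefficientMatrix) else matrix
    if isinstance(vals, pd.DataFrame):
        index = vals.index
        arr = vals.to_numpy(dtype=float)
    else:
        arr = np.asarray(vals, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    Z = ward_cluster(arr)
    heights = Z[:, 2]
    n = arr.shape[0]

    rng = np.random.default_rng([seed % (2**31), 8])
    perm_heights = np.empty((n_perm, n - 1))
    work = np.empty_like(arr)
    for i in range(n_perm):
        for j in range(arr.shape[1]):
            work[:, j] = arr[rng.permutation(n), j]
        perm_heights[i] = hierarchy.linkage(work, method="ward")[:, 2]
    perm_max = perm_heights.max(axis=1)

    if mode == "max_height":
        envelope = perm_max.max()
        above = heights > envelope
    elif mode == "per_merge":
        # a merge is significant when its height exceeds every permutation's
        # height at the same merge index; counted contiguously from the top
        # of the tree so k-1 significant top merges yield k clusters
        exceeds = heights > perm_heights.max(axis=0)
        above = np.zeros_like(exceeds)
        j = len(exceeds) - 1
        while j >= 0 and exceeds[j]:
            above[j] = True
            j -= 1
    else:
        raise ValueError("mode must be 'max_height' or 'per_merge'")

    if not above.any():
        assignments = pd.Series(1, index=index, name="cluster")
        return ClusterSolution(
            linkage=Z,
            merge_heights=heights,
            k=1,
            assignments=assignments,
            perm_max_heights=perm_max,
            p=1.0,
            cut_height=np.nan,
        )
    first = int(np.argmax(above))
    cut_height = float(heights[first])
    k = (n - 1) - first + 1  # merges at or above the cut stay separate
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    p = (1 + int((perm_max >= cut_height).sum())) / (1 + n_perm)
    return ClusterSolution(
        linkage=Z,
        merge_heights=heights,
        k=int(k),
        assignments=pd.Series(labels, index=index, name="cluster"),
        perm_max_heights=perm_max,
        p=float(p),
        cut_height=cut_height,
    )


def dendrogram_newick(Z: np.ndarray, labels=None) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths.

    Branch lengths are differences of merge heights (leaves sit at height
    0), so the tree can be rendered by any standard phylogenetics viewer.
    """
    from scipy.cluster import hierarchy

    tree = hierarchy.to_tree(Z)
    n = tree.get_count()
    if labels is None:
        labels = [f"row{i}" for i in range(n)]

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"
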