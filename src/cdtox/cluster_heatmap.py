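"""Pooled-timepoint variance filtering and Pearson/Ward hierarchical clustering.

The pooled 8-sample matrix is shifted by a single global constant so its grand
mean is zero, genes with standard deviation above a threshold are retained as
the "high-variability" set, samples are clustered on Pearson dissimilarity
(d = 1 - r) with Ward linkage, and genes are clustered the same way solely to
order heat-map columns.

Ward dialect: the default is the squared-dissimilarity (Ward.D2) formulation,
i.e. what ``scipy.cluster.hierarchy.linkage(method="ward")`` computes on a
condensed distance matrix; the historical unsquared variant (``ward_d1``) is
available behind a flag and is computed by an explicit Lance-Williams
recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CenteredMatrix",
    "center_and_filter",
    "pearson_dissimilarity",
    "Dendrogram",
    "hierarchical_cluster",
    "ward_cluster",
    "cut_tree",
    "lance_williams_linkage",
    "plot_heatmap",
]

LINKAGES = ("ward", "ward_d1", "average", "complete")


@dataclass
class CenteredMatrix:
    """Grand-mean-centered matrix with the SD filter applied.

    ``values`` holds all genes (centered); ``mask`` marks the genes whose
    across-sample SD (ddof=1) strictly exceeds the threshold; ``retained``
    is the filtered sub-matrix.
    """

    values: pd.DataFrame
    gene_sd: pd.Series
    sd_threshold: float
    mask: pd.Series

    @property
    def retained(self) -> pd.DataFrame:
        return self.values.loc[self.mask]


def center_and_filter(matrix, sd_threshold: float = 1.0) -> CenteredMatrix:
    """Center a genes x samples matrix to grand mean 0 and filter by SD.

    Accepts an ExpressionStudy (its signal is used) or a DataFrame.  The
    grand mean is a single global constant over all entries; per-gene SD uses
    the n-1 denominator and the filter is strict (SD > threshold), so a
    constant gene is excluded even at threshold 0.
    """
    if sd_threshold < 0:
        raise ValueError(f"sd_threshold must be >= 0, got {sd_threshold}")
    if hasattr(matrix, "signal"):
        matrix = matrix.signal
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    centered = matrix - matrix.to_numpy().mean()
    sd = centered.std(axis=1, ddof=1)
    mask = sd > sd_threshold
    return CenteredMatrix(values=centered, gene_sd=sd, sd_threshold=sd_threshold, mask=mask)


def pearson_dissimilarity(matrix: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pearson dissimilarity d = 1 - r between rows or columns.

    ``axis="columns"`` compares samples (column vectors), ``axis="rows"``
    compares genes.  d is symmetric, zero on the diagonal and in [0, 2];
    a zero-variance vector is rejected with its id.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    X = matrix.to_numpy(dtype=float)
    ids = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "columns":
        X = X.T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compare")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance vector {bad!r}; Pearson undefined")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """An agglomerative clustering result over named leaves.

    ``merges`` is a scipy-style linkage matrix: row i merges clusters
    ``child_a`` and ``child_b`` (ids < n are leaves) at ``height`` into
    cluster n + i.
    """

    merges: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.leaves[i] for i in order]

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges[:, :3], columns=["child_a", "child_b", "height"]
        ).astype({"child_a": int, "child_b": int})

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        height_of = {i: 0.0 for i in range(n)}
        node = {i: self.leaves[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height_of[a], 0.0)
            lb = max(h - height_of[b], 0.0)
            node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height_of[n + i] = h
        return node[n + self.merges.shape[0] - 1] + ";"


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix is not square: {D.shape}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def hierarchical_cluster(dist: pd.DataFrame, method: str = "ward") -> Dendrogram:
    """Agglomerative clustering of a labeled distance matrix.

    ``method``: "ward" (Ward.D2 dialect), "ward_d1" (historical unsquared
    Ward via Lance-Williams), "average" or "complete".
    """
    if method not in LINKAGES:
        raise ValueError(f"method must be one of {LINKAGES}, got {method!r}")
    D = _check_distance(dist)
    labels = list(dist.index)
    if method == "ward_d1":
        merges = lance_williams_linkage(D, method="ward_d1")
    else:
        scipy_method = "ward" if method == "ward" else method
        merges = hierarchy.linkage(squareform(D, checks=False), method=scipy_method)
    return Dendrogram(merges=merges, leaves=labels)


def ward_cluster(dist: pd.DataFrame, dialect: str = "ward") -> Dendrogram:
    """Ward-linkage clustering (default squared-dissimilarity dialect)."""
    if dialect not in ("ward", "ward_d1"):
        raise ValueError(f"dialect must be 'ward' or 'ward_d1', got {dialect!r}")
    return hierarchical_cluster(dist, method=dialect)


def lance_williams_linkage(D: np.ndarray, method: str = "ward_d1") -> np.ndarray:
    """Naive O(n^3) agglomeration by the Lance-Williams update.

    Implements the unsquared (historical) Ward dialect: the update
    d(k, i+j) = [(n_k+n_i) d(k,i) + (n_k+n_j) d(k,j) - n_k d(i,j)] / (n_k+n_i+n_j)
    is applied to the dissimilarities as given.  Also usable as an
    independent oracle for the scipy-backed linkages ("average",
    "complete", "ward_d2" applying the same update to squared distances with
    a final square root).
    """
    if method not in ("ward_d1", "ward_d2", "average", "complete"):
        raise ValueError(f"unsupported method {method!r}")
    D = D.astype(float).copy()
    n = D.shape[0]
    if method == "ward_d2":
        D = D**2
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    merges = []
    next_id = n
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    slots = list(range(n))
    for step in range(n - 1):
        sub = work[np.ix_(slots, slots)]
        flat = np.argmin(sub)
        ii, jj = divmod(flat, len(slots))
        if ii > jj:
            ii, jj = jj, ii
        si, sj = slots[ii], slots[jj]
        d_ij = work[si, sj]
        id_i, n_i = active[si]
        id_j, n_j = active[sj]
        height = np.sqrt(d_ij) if method == "ward_d2" else d_ij
        a, b = sorted((id_i, id_j))
        merges.append([a, b, height, n_i + n_j])
        for sk in slots:
            if sk in (si, sj):
                continue
            _, n_k = active[sk]
            d_ki, d_kj = work[sk, si], work[sk, sj]
            if method == "average":
                new = (n_i * d_ki + n_j * d_kj) / (n_i + n_j)
            elif method == "complete":
                new = max(d_ki, d_kj)
            else:  # ward (D1 on raw, D2 on squared input)
                new = (
                    (n_k + n_i) * d_ki + (n_k + n_j) * d_kj - n_k * d_ij
                ) / (n_k + n_i + n_j)
            work[sk, si] = work[si, sk] = new
        active[si] = (next_id, n_i + n_j)
        next_id += 1
        slots.remove(sj)
    return np.asarray(merges, dtype=float)


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut a dendrogram into exactly k clusters.

    Returns a Series mapping leaf id -> cluster label in {0..k-1}; labels are
    assigned by first appearance in leaf-input order, so they are stable
    across runs.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(dendrogram.merges, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
        labels.append(remap[lab])
    return pd.Series(labels, index=dendrogram.leaves, name="cluster")


def plot_heatmap(
    centered: CenteredMatrix,
    sample_dendro: Dendrogram | None = None,
    gene_dendro: Dendrogram | None = None,
    path=None,
    matrix_path=None,
):
    """Render the retained (samples x genes) heat map, rows/columns ordered
    by the dendrograms; optionally write the image and the ordered matrix TSV.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = centered.retained  # genes x samples
    sample_order = sample_dendro.leaf_order() if sample_dendro else list(mat.columns)
    gene_order = gene_dendro.leaf_order() if gene_dendro else list(mat.index)
    ordered = mat.loc[gene_order, sample_order]
    if matrix_path is not None:
        ordered.rename_axis("gene").to_csv(matrix_path, sep="\t", float_format="%.6g")
    fig, ax = plt.subplots(figsize=(10, 3 + 0.25 * len(sample_order)))
    disp = ordered.T  # samples as rows, genes as columns, as in the study's figure
    vmax = np.nanpercentile(np.abs(disp.to_numpy()), 98) or 1.0
    im = ax.imshow(disp, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(sample_order)), sample_order, fontsize=8)
    ax.set_xticks([])
    ax.set_xlabel(f"{len(gene_order)} high-variability genes")
    fig.colorbar(im, ax=ax, shrink=0.7, label="centered signal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
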