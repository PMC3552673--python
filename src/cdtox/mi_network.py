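"""Mutual-information coexpression network and module detection.

With only 8 arrays, relations between the high-variability genes are scored
by plug-in mutual information on equal-frequency bins (B = 3 by default):
MI is distribution-free and captures the sign-free co-regulation that a
small-n correlation would need direction assumptions for.  The MI adjacency
is turned into a bounded distance (1 - normalized MI by default),
hierarchically clustered (average linkage), and every cluster appearing in a
range of tree cuts is scored by its separation = mean intra-pair MI minus
mean MI to non-members.  A network module is a cluster with positive
separation; the top-ranked one is "the most prominent module".

Raw plug-in MI at n = 8 is strongly biased upward, but the bias is common to
all pairs, so module significance is judged against a permutation null
(independently shuffling each gene's profile) rather than against absolute
MI; an optional Miller-Madow correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_heatmap import CenteredMatrix, Dendrogram, cut_tree, hierarchical_cluster

__all__ = [
    "discretize",
    "entropy_bits",
    "mutual_information",
    "MIMatrix",
    "mi_adjacency",
    "mi_distance",
    "NetworkModule",
    "detect_modules",
    "permutation_null_separation",
    "export_network",
]

SCHEMES = ("equal_frequency", "equal_width")
DISTANCE_MODES = ("one_minus_nmi", "max_shift")


def default_bins(n_samples: int) -> int:
    """Square-root rule for the bin count: floor(sqrt(n)), at least 2."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return max(2, int(np.floor(np.sqrt(n_samples))))


def discretize(matrix, B: int = 3, scheme: str = "equal_frequency") -> np.ndarray:
    """Bin each gene's profile independently into B integer labels.

    equal_frequency: ranks are split into B nearly equal bins (sizes differ
    by at most 1, earlier bins take the remainder); ties are broken by value
    order then input order (stable sort), except that a constant gene
    collapses to a single occupied bin (all labels 0).
    equal_width: B equal-width bins over each gene's [min, max].

    Accepts a DataFrame or 2-D array (genes x samples) or a 1-D profile;
    returns an int array of the same shape.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    X = np.asarray(matrix, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    n = X.shape[1]
    if B > n:
        raise ValueError(f"B={B} bins but only {n} samples")
    labels = np.zeros(X.shape, dtype=np.int64)
    if scheme == "equal_frequency":
        sizes = np.diff(np.linspace(0, n, B + 1).round().astype(int))
        bin_of_rank = np.repeat(np.arange(B), sizes)
        for g in range(X.shape[0]):
            row = X[g]
            if row.max() == row.min():
                continue  # constant: single occupied bin
            order = np.argsort(row, kind="stable")
            labels[g, order] = bin_of_rank
    else:
        for g in range(X.shape[0]):
            row = X[g]
            lo, hi = row.min(), row.max()
            if hi == lo:
                continue
            edges = np.linspace(lo, hi, B + 1)
            labels[g] = np.clip(np.searchsorted(edges, row, side="right") - 1, 0, B - 1)
    return labels[0] if single else labels


def entropy_bits(labels, B: int | None = None) -> float:
    """Plug-in Shannon entropy (bits) of a label vector."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=B or 0).astype(float)
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(x_labels, y_labels, B: int | None = None) -> float:
    """Plug-in MI (bits) between two label vectors from their joint histogram.

    MI = sum_ab p(a,b) log2[ p(a,b) / (p(a) p(b)) ], with 0 log 0 := 0.
    """
    x = np.asarray(x_labels)
    y = np.asarray(y_labels)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if B is None:
        B = int(max(x.max(), y.max())) + 1
    n = x.size
    joint = np.bincount(x * B + y, minlength=B * B).reshape(B, B).astype(float) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    mi = float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())
    return max(mi, 0.0)


@dataclass
class MIMatrix:
    """Symmetric gene x gene MI (bits); diagonal is the per-gene entropy."""

    mi: pd.DataFrame
    entropy: pd.Series
    B: int
    scheme: str
    miller_madow: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.mi.index)


def mi_adjacency(
    matrix,
    B: int = 3,
    scheme: str = "equal_frequency",
    miller_madow: bool = False,
) -> MIMatrix:
    """All pairwise plug-in MI over a genes x samples matrix.

    Accepts a CenteredMatrix (its retained genes are used — the network is
    built on the variance-filtered set only), a DataFrame, or an array.
    Computed with one-hot matrix products, so the full matrix is exact and
    fast for the few hundred genes this pipeline retains.  The optional
    Miller-Madow correction adds (occupied_cells - 1)/(2 n ln 2) to entropies
    and subtracts the analogous joint term from MI.
    """
    if isinstance(matrix, CenteredMatrix):
        matrix = matrix.retained
    if isinstance(matrix, pd.DataFrame):
        genes = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        genes = [f"g{i}" for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes for an adjacency")
    L = discretize(X, B=B, scheme=scheme)
    G, n = L.shape
    onehot = np.stack([(L == b).astype(float) for b in range(B)])  # B x G x n
    marg = onehot.sum(axis=2) / n                                   # B x G
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.where(marg > 0, marg * np.log2(marg), 0.0).sum(axis=0)
    mi = np.zeros((G, G))
    occupied = np.zeros((G, G))
    for a in range(B):
        for b in range(B):
            joint = onehot[a] @ onehot[b].T / n                     # G x G
            outer = marg[a][:, None] * marg[b][None, :]
            nz = joint > 0
            term = np.zeros_like(joint)
            term[nz] = joint[nz] * np.log2(joint[nz] / outer[nz])
            mi += term
            occupied += nz
    mi = np.maximum(mi, 0.0)
    if miller_madow:
        k_marg = (marg > 0).sum(axis=0).astype(float)
        H = H + (k_marg - 1) / (2 * n * np.log(2))
        mi = mi + (
            (k_marg[:, None] - 1) + (k_marg[None, :] - 1) - (occupied - 1)
        ) / (2 * n * np.log(2))
        mi = np.maximum(mi, 0.0)
    mi = (mi + mi.T) / 2.0
    np.fill_diagonal(mi, H)
    return MIMatrix(
        mi=pd.DataFrame(mi, index=genes, columns=genes),
        entropy=pd.Series(H, index=genes),
        B=B,
        scheme=scheme,
        miller_madow=miller_madow,
    )


def mi_distance(mim: MIMatrix, mode: str = "one_minus_nmi") -> pd.DataFrame:
    """Turn an MI adjacency into a bounded distance matrix.

    one_minus_nmi: d_ij = 1 - MI_ij / sqrt(H_i H_j), in [0, 1] with d_ii = 0;
    a zero-entropy gene's distances are set to 1 (and flagged via
    ``d.attrs['zero_entropy']``).
    max_shift: d_ij = (max MI - MI_ij) rescaled to [0, 1].
    """
    if mode not in DISTANCE_MODES:
        raise ValueError(f"mode must be one of {DISTANCE_MODES}, got {mode!r}")
    M = mim.mi.to_numpy().copy()
    H = mim.entropy.to_numpy()
    G = M.shape[0]
    if mode == "one_minus_nmi":
        zero = H <= 0
        denom = np.sqrt(np.outer(np.where(zero, 1.0, H), np.where(zero, 1.0, H)))
        d = 1.0 - M / denom
        d[zero, :] = 1.0
        d[:, zero] = 1.0
        flagged = list(mim.entropy.index[zero])
    else:
        off = ~np.eye(G, dtype=bool)
        top = M[off].max() if G > 1 else 1.0
        span = top - (M[off].min() if G > 1 else 0.0)
        d = (top - M) / (span if span > 0 else 1.0)
        flagged = []
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    out = pd.DataFrame(d, index=mim.mi.index, columns=mim.mi.columns)
    out.attrs["zero_entropy"] = flagged
    return out


@dataclass(frozen=True)
class NetworkModule:
    """A candidate module: short distances inside, long to everything else."""

    members: tuple[str, ...]
    intra: float       # mean pairwise MI inside the module
    extra: float       # mean MI from members to non-members
    separation: float  # intra - extra

    @property
    def size(self) -> int:
        return len(self.members)


def _score_cluster(M: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    inside = M[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    intra = float(inside[iu].mean())
    rest = np.setdiff1d(np.arange(M.shape[0]), idx)
    extra = float(M[np.ix_(idx, rest)].mean()) if rest.size else 0.0
    return intra, extra


def detect_modules(
    mim: MIMatrix,
    mode: str = "one_minus_nmi",
    linkage: str = "average",
    min_size: int = 4,
    n_candidate_cuts: int = 30,
    dist: pd.DataFrame | None = None,
) -> list[NetworkModule]:
    """Find network modules by clustering the MI-derived distance matrix.

    Every cluster of size >= min_size appearing in tree cuts k = 2 ..
    n_candidate_cuts+1 (capped at G-1) is scored on the MI matrix by
    separation = intra - extra.  Candidates from different cuts are nested,
    so the reported modules are a greedy non-overlapping selection: best
    separation first, then the best candidate disjoint from everything
    already reported, and so on.  Ties break on smaller size then member ids
    so the output is deterministic.  An empty list (nothing of size >=
    min_size, or nothing separated) is a valid result.
    """
    if min_size < 3:
        raise ValueError(f"min_size must be >= 3, got {min_size}")
    genes = mim.genes
    G = len(genes)
    off_diag = mim.mi.to_numpy().copy()
    if dist is None:
        dist = mi_distance(mim, mode=mode)
    dendro = hierarchical_cluster(dist, method=linkage)
    seen: set[frozenset] = set()
    modules: list[NetworkModule] = []
    for k in range(2, min(n_candidate_cuts + 2, G)):
        labels = cut_tree(dendro, k).to_numpy()
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if not (min_size <= idx.size < G):
                continue
            key = frozenset(idx.tolist())
            if key in seen:
                continue
            seen.add(key)
            intra, extra = _score_cluster(off_diag, idx)
            sep = intra - extra
            if sep > 0:
                modules.append(
                    NetworkModule(
                        members=tuple(genes[i] for i in idx),
                        intra=intra,
                        extra=extra,
                        separation=sep,
                    )
                )
    modules.sort(key=lambda m: (-m.separation, m.size, m.members))
    taken: set[str] = set()
    disjoint = []
    for m in modules:
        if taken.isdisjoint(m.members):
            disjoint.append(m)
            taken.update(m.members)
    return disjoint


def permutation_null_separation(
    matrix,
    B: int = 3,
    scheme: str = "equal_frequency",
    n_permutations: int = 50,
    rng: np.random.Generator | int | None = None,
    **detect_kwargs,
) -> np.ndarray:
    """Null distribution of the top-module separation under independence.

    Each permutation shuffles every gene's profile independently (destroying
    gene-gene dependence while preserving marginals), rebuilds the MI
    adjacency, reruns module detection, and records the best separation
    (0 when no module is found).
    """
    rng = np.random.default_rng(rng)
    if isinstance(matrix, CenteredMatrix):
        matrix = matrix.retained
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    out = np.zeros(n_permutations)
    for i in range(n_permutations):
        perm = np.array([rng.permutation(row) for row in X])
        mim = mi_adjacency(perm, B=B, scheme=scheme)
        mods = detect_modules(mim, **detect_kwargs)
        out[i] = mods[0].separation if mods else 0.0
    return out


def export_network(
    mim: MIMatrix,
    dist: pd.DataFrame,
    modules: list[NetworkModule],
    edge_path=None,
    module_path=None,
    mi_path=None,
    edge_quantile: float = 0.9,
):
    """Write the MI matrix, a thresholded weighted edge list, and module
    membership as TSVs; returns the networkx graph of retained edges."""
    import networkx as nx

    M = mim.mi.to_numpy()
    genes = mim.genes
    iu = np.triu_indices(len(genes), k=1)
    weights = M[iu]
    thresh = np.quantile(weights, edge_quantile) if weights.size else 0.0
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    rows = []
    for a, b, w in zip(*iu, weights):
        if w >= thresh:
            graph.add_edge(genes[a], genes[b], mi=float(w), distance=float(dist.iat[a, b]))
            rows.append((genes[a], genes[b], w, dist.iat[a, b]))
    if edge_path is not None:
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "distance"]).to_csv(
            edge_path, sep="\t", index=False, float_format="%.6g"
        )
    if module_path is not None:
        mrows = [
            (rank, gene, m.size, m.intra, m.extra, m.separation)
            for rank, m in enumerate(modules, start=1)
            for gene in m.members
        ]
        pd.DataFrame(
            mrows, columns=["module_rank", "gene", "size", "intra_mi", "extra_mi", "separation"]
        ).to_csv(module_path, sep="\t", index=False, float_format="%.6g")
    if mi_path is not None:
        mim.mi.rename_axis("gene").to_csv(mi_path, sep="\t", float_format="%.6g")
    return graph
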