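"""Hierarchical clustering of libraries with multiscale-bootstrap support.

Libraries are clustered on Pearson-correlation distance (``1 - r`` between
the per-site profiles of two libraries).  Cluster uncertainty is assessed by
resampling *sites* (features) with replacement at several scale factors r of
the original feature count, reclustering each resample, and recording for
every cluster of the original tree the fraction of resample trees containing
the same leaf set (BP_r).  The ordinary bootstrap probability BP is BP_r at
the scale closest to 1.  The approximately unbiased (AU) value corrects the
scale dependence: for scales with 0 < BP_r < 1 the probit-transformed
curve ``z_r = Phi^-1(1 - BP_r)`` is fit by weighted least squares to
``z_r = v*sqrt(r) + c/sqrt(r)`` and ``AU = 1 - Phi(v - c)``.  Clusters with
AU above 0.95 are conventionally read as strongly supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5..1.4

_LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterNode:
    leaves: frozenset  # leaf indices
    height: float
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None
    au: float | None = None
    bp: float | None = None
    degenerate: bool = False  # AU taken from degenerate BP, not the fit

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ClusterTree:
    labels: list[str]
    root: ClusterNode
    internal_nodes: list[ClusterNode]  # in merge order

    def leaf_labels(self, node: ClusterNode) -> frozenset:
        return frozenset(self.labels[i] for i in node.leaves)

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for node in self.internal_nodes:
            rows.append({
                "members": ",".join(sorted(self.leaf_labels(node))),
                "n_leaves": len(node.leaves),
                "height": node.height,
                "au": node.au,
                "bp": node.bp,
                "degenerate": node.degenerate,
            })
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        def fmt(node: ClusterNode) -> str:
            if node.is_leaf:
                (i,) = node.leaves
                return self.labels[i]
            inner = f"{fmt(node.left)},{fmt(node.right)}"
            support = ""
            if node.au is not None:
                support = f"[&&au={100 * node.au:.1f},bp={100 * node.bp:.1f}]"
            return f"({inner}){support}:{node.height:.6g}"

        return fmt(self.root) + ";"


def _as_values(matrix) -> pd.DataFrame:
    """Accept a TagCountMatrix, NormalizedMatrix or plain DataFrame."""
    for attr in ("values", "counts"):
        inner = getattr(matrix, attr, None)
        if isinstance(inner, pd.DataFrame):
            return inner
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"cannot extract a sites x libraries table from "
                    f"{type(matrix).__name__}")


def correlation_distance(matrix) -> pd.DataFrame:
    """Pearson-correlation distance ``1 - r`` between library columns."""
    values = _as_values(matrix)
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValueError("need >= 2 libraries and >= 2 sites")
    sd = values.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero variance in library {zero.index[0]!r}")
    corr = np.corrcoef(values.to_numpy(float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=values.columns, columns=values.columns)


def _corr_dist_array(X: np.ndarray) -> np.ndarray:
    """1 - corr for a resampled matrix; zero-variance columns -> r = 0."""
    Xc = X - X.mean(axis=0)
    ss = np.sqrt((Xc * Xc).sum(axis=0))
    ss[ss == 0] = np.inf  # constant column: correlation treated as 0
    corr = (Xc.T @ Xc) / np.outer(ss, ss)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def _merge_sequence(
    D: np.ndarray, linkage: str, iu: tuple[np.ndarray, np.ndarray]
) -> list[tuple[int, int, float]]:
    """Agglomerative merge order on a small distance matrix.

    Ties are broken by the smallest (i, j) index pair (row-major order of
    the upper triangle).  Returns (i, j, height) with cluster j absorbed
    into i.
    """
    n = D.shape[0]
    D = D.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    merges = []
    for _ in range(n - 1):
        M = np.where(active[:, None] & active[None, :], D, np.inf)
        flat = M[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])
        h = float(M[i, j])
        if linkage == "average":
            new = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        elif linkage == "complete":
            new = np.maximum(D[i], D[j])
        else:  # single
            new = np.minimum(D[i], D[j])
        D[i] = new
        D[:, i] = new
        D[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        merges.append((i, j, h))
    return merges


def hierarchical_cluster(
    dist: pd.DataFrame, linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Deterministic: equal merge distances are resolved by the smallest
    (i, j) index pair.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    D = dist.to_numpy(float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    labels = (list(dist.columns) if isinstance(dist, pd.DataFrame)
              else [str(i) for i in range(D.shape[0])])
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    node_of: list[ClusterNode] = [ClusterNode(frozenset([i]), 0.0)
                                  for i in range(n)]
    internal = []
    for i, j, h in _merge_sequence(D, linkage, iu):
        node = ClusterNode(node_of[i].leaves | node_of[j].leaves, h,
                           left=node_of[i], right=node_of[j])
        node_of[i] = node
        internal.append(node)
    return ClusterTree(labels, internal[-1], internal)


def _leafsets(merges: Sequence[tuple[int, int, float]], n: int) -> list[frozenset]:
    members = [frozenset([i]) for i in range(n)]
    out = []
    for i, j, _ in merges:
        members[i] = members[i] | members[j]
        out.append(members[i])
    return out


def _fit_au(scales: np.ndarray, bp_r: np.ndarray, B: int) -> tuple[float, bool]:
    """Shimodaira probit fit across scales -> AU value, degeneracy flag."""
    usable = (bp_r > 0) & (bp_r < 1)
    if usable.sum() < 2:
        vals = set(np.round(bp_r, 12))
        if vals <= {0.0, 1.0} and len(vals) == 1:
            return float(bp_r[0]), True
        # mixed degenerate curve or a single usable point: fall back to the
        # BP nearest scale 1
        idx = int(np.argmin(np.abs(scales - 1.0)))
        return float(bp_r[idx]), True
    r = scales[usable]
    bp = bp_r[usable]
    z = norm.ppf(1.0 - bp)
    w = B * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    A = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    Aw = A * w[:, None]
    beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ z, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = 1.0 - norm.cdf(v - c)
    return float(np.clip(au, 0.0, 1.0)), False


def multiscale_bootstrap(
    matrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int = 0,
    linkage: str = "average",
) -> ClusterTree:
    """Cluster libraries and attach AU/BP support to every internal node.

    Sites (rows) are resampled with replacement, ``round(r * n)`` rows at
    each scale ``r``, ``B`` resamples per scale; libraries are never
    resampled.  The root carries au = bp = 1 by convention.  The output is
    fully determined by (matrix, scales, B, seed).
    """
    values = _as_values(matrix)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sites to resample")
    scales = np.asarray(sorted(scales), dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if B < 100:
        raise ValueError("B must be >= 100")

    tree = hierarchical_cluster(correlation_distance(values), linkage)
    n_libs = values.shape[1]
    iu = np.triu_indices(n_libs, 1)
    X = values.to_numpy(float)

    cluster_ids = {tree_node.leaves: k
                   for k, tree_node in enumerate(tree.internal_nodes)}
    hits = np.zeros((len(cluster_ids), len(scales)), dtype=np.int64)

    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        m = max(2, int(round(r * n)))
        for _ in range(B):
            idx = rng.integers(0, n, size=m)
            D = _corr_dist_array(X[idx])
            for ls in _leafsets(_merge_sequence(D, linkage, iu), n_libs):
                k = cluster_ids.get(ls)
                if k is not None:
                    hits[k, si] += 1

    bp_all = hits / float(B)
    near_one = int(np.argmin(np.abs(scales - 1.0)))
    for node, k in cluster_ids.items():
        tn = tree.internal_nodes[cluster_ids[node]]
        tn.bp = float(bp_all[k, near_one])
        tn.au, tn.degenerate = _fit_au(scales, bp_all[k], B)
    tree.root.au = 1.0
    tree.root.bp = 1.0
    tree.root.degenerate = False
    return tree


def write_newick(tree: ClusterTree, path: str | Path,
                 header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"[{header}]\n")
        fh.write(tree.to_newick() + "\n")
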