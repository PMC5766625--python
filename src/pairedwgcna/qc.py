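"""Sample-level quality control.

PCA overview, sample-dendrogram outlier flagging, and pair-consistent sample
exclusion: when a sample is flagged, its matched partner is removed too, so
the design stays fully paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .data_io import ExpressionMatrix, PairedDesign
from .errors import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "QCReport",
    "pca_overview",
    "flag_outlier_samples",
    "exclude_pairs",
    "quantile_normalize",
    "sample_tree_newick",
]


@dataclass
class QCReport:
    """Container for sample-QC results; fields are filled in stages."""

    pc_scores: pd.DataFrame | None = None          # samples x k
    pc_variance_fraction: np.ndarray | None = None  # length k, non-increasing
    sample_tree: np.ndarray | None = None           # scipy linkage matrix
    sample_order: list[str] = field(default_factory=list)
    flagged_samples: list[str] = field(default_factory=list)
    excluded_pairs: list[str] = field(default_factory=list)


def pca_overview(expr: ExpressionMatrix, k: int = 2) -> QCReport:
    """Project samples onto the top-k principal axes after per-gene centering.

    Returns a QCReport with ``pc_scores`` (samples x k) and
    ``pc_variance_fraction`` (eigenvalue fractions of the sample covariance).
    """
    if k < 1 or k > min(expr.n_genes, expr.n_samples):
        raise ValueError(f"k={k} out of range for {expr.n_genes} genes x {expr.n_samples} samples")
    X = expr.values.T.astype(float)              # samples x genes
    X = X - X.mean(axis=0, keepdims=True)        # per-gene centering
    total_var = float(np.sum(X * X))
    if total_var == 0.0:
        raise DegenerateDataError("constant expression matrix: PCA is undefined")
    # SVD of the centered sample x gene matrix
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    frac = (s**2) / np.sum(s**2)
    report = QCReport()
    report.pc_scores = pd.DataFrame(
        scores, index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    report.pc_variance_fraction = frac[:k]
    return report


def _standardize_genes(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes contribute zero distance
    return (values - mu) / sd


def _leaf_merge_heights(Z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original observation is first merged."""
    heights = np.empty(n)
    merged = np.zeros(n, dtype=bool)
    # walk linkage rows; each row merges clusters Z[i,0], Z[i,1] at Z[i,2]
    members: list[list[int]] = [[i] for i in range(n)]
    for a, b, h, _ in Z:
        a, b = int(a), int(b)
        for cl in (a, b):
            if cl < n and not merged[cl]:
                heights[cl] = h
                merged[cl] = True
        members.append(members[a] + members[b])
    heights[~merged] = 0.0
    return heights


def flag_outlier_samples(expr: ExpressionMatrix, z_cut: float = 2.5) -> list[str]:
    """Flag samples whose dendrogram merge height is an outlier.

    Average-linkage clustering on Euclidean distance over standardized
    genes; a sample is flagged when the height at which it first merges
    exceeds mean + z_cut * sd of all leaf merge heights.  Deterministic;
    may return an empty list (z_cut = inf always does).
    """
    if expr.n_samples < 4:
        raise InsufficientDataError("outlier flagging needs >=4 samples")
    Xs = _standardize_genes(expr.values)
    D = pdist(Xs.T, metric="euclidean")
    Z = linkage(D, method="average")
    h = _leaf_merge_heights(Z, expr.n_samples)
    if not np.isfinite(z_cut):
        return []
    sd = h.std(ddof=1)
    if sd == 0:
        return []
    thresh = h.mean() + z_cut * sd
    return [s for s, hi in zip(expr.sample_ids, h) if hi > thresh]


def sample_tree(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over samples (Euclidean on standardized genes)."""
    Xs = _standardize_genes(expr.values)
    Z = linkage(pdist(Xs.T, metric="euclidean"), method="average")
    return Z, list(expr.sample_ids)


def sample_tree_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    root = to_tree(Z)

    def rec(node, parent_h: float) -> str:
        length = max(parent_h - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = rec(root, root.dist)
    # strip the root's zero-length suffix
    return body.rsplit(":", 1)[0] + ";"


def exclude_pairs(
    expr: ExpressionMatrix,
    design: PairedDesign,
    flagged: list[str],
    min_pairs: int = 3,
) -> tuple[ExpressionMatrix, PairedDesign, list[str]]:
    """Remove both samples of every pair that contains a flagged sample.

    Returns the reduced matrix, the reduced (re-validated) design, and the
    list of excluded pair ids.  Raises if fewer than ``min_pairs`` complete
    pairs would remain.
    """
    unknown = sorted(set(flagged) - set(design.sample_ids))
    if unknown:
        raise ValidationError(f"flagged samples not in design: {unknown}")
    if not flagged:
        return expr, design, []
    pair_of = dict(zip(design.sample_ids, design.pair_ids))
    bad_pairs = sorted({pair_of[s] for s in flagged})
    keep_samples = [s for s, p in zip(design.sample_ids, design.pair_ids) if p not in bad_pairs]
    n_left = len(keep_samples) // 2
    if n_left < min_pairs:
        raise InsufficientDataError(
            f"excluding pairs {bad_pairs} leaves {n_left} pairs (< {min_pairs})"
        )
    new_design = design.subset(keep_samples)
    kept_cols = [s for s in expr.sample_ids if s in set(keep_samples)]
    new_expr = expr.subset_samples(kept_cols)
    return new_expr, new_design, bad_pairs


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Optional quantile normalization across samples (off by default in the
    pipeline; provided because upstream array preprocessing varies)."""
    V = expr.values
    order = np.argsort(V, axis=0)
    ranks = np.empty_like(order)
    n_genes = V.shape[0]
    rows = np.arange(n_genes)
    for j in range(V.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(V, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), out)
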