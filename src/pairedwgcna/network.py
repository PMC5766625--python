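"""Weighted co-expression network construction.

Similarity = |Pearson correlation| over all pooled samples (valid for paired
designs by the two-component mixture identity implemented in
:func:`mixture_correlation`), soft-threshold adjacency, scale-free fit scan,
and the unsigned topological overlap matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import DegenerateDataError, DomainError

__all__ = [
    "SimilarityMatrix",
    "AdjacencyMatrix",
    "ScaleFreeScan",
    "TOMMatrix",
    "MixtureParams",
    "similarity",
    "mixture_correlation",
    "adjacency",
    "scale_free_scan",
    "tom",
]


@dataclass
class SimilarityMatrix:
    """Absolute-correlation similarity: symmetric, unit diagonal, in [0,1]."""

    gene_ids: list[str]
    s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded adjacency a = s**beta with zero diagonal (so that
    row sums are the whole-network connectivity k)."""

    gene_ids: list[str]
    a: np.ndarray
    beta: int

    def connectivity(self) -> np.ndarray:
        return self.a.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ScaleFreeScan:
    beta_grid: list[int]
    r2: np.ndarray                  # signed fit index per beta
    mean_connectivity: np.ndarray   # per beta
    chosen_beta: int
    k: np.ndarray                   # per-gene connectivity at chosen beta
    pk_bins: pd.DataFrame           # binned (mean_k, frequency) at chosen beta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta_grid, "r2": self.r2, "mean_k": self.mean_connectivity}
        )


@dataclass
class TOMMatrix:
    gene_ids: list[str]
    tom: np.ndarray

    @property
    def diss(self) -> np.ndarray:
        return 1.0 - self.tom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tom, index=self.gene_ids, columns=self.gene_ids)


def similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """s_ij = |Pearson correlation of genes i and j| over all samples,
    cases and controls pooled."""
    expr.validate_for_network()
    V = expr.values
    sd = V.std(axis=1, ddof=1)
    zero = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if zero:
        raise DegenerateDataError(f"zero-variance genes: {zero}")
    s = np.abs(np.corrcoef(V))
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    s = (s + s.T) / 2.0
    return SimilarityMatrix(list(expr.gene_ids), s)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the two-component (control/case) mixture of a gene pair.

    p is the case fraction; cov_x / cov_y the between-gene covariances in
    controls / cases; var_* the component variances; delta1/delta2 the
    case-minus-control mean shifts of the two genes.
    """

    p: float
    cov_x: float
    cov_y: float
    var_x1: float
    var_x2: float
    var_y1: float
    var_y2: float
    delta1: float = 0.0
    delta2: float = 0.0


def mixture_correlation(params: MixtureParams) -> float:
    """Closed-form Pearson correlation of the two-component mixture.

    With Z_i = (1-theta) X_i + theta Y_i and theta ~ Bernoulli(p):

        corr(Z1, Z2) = [(1-p) cov_x + p cov_y + p(1-p) d1 d2] /
                       sqrt(((1-p) vx1 + p vy1 + p(1-p) d1^2) *
                            ((1-p) vx2 + p vy2 + p(1-p) d2^2))

    This identity holds whether or not samples are paired, which is what
    justifies pooled Pearson similarity on paired data.
    """
    q = params.p
    if not 0.0 < q < 1.0:
        raise DomainError(f"p must be in (0,1), got {q}")
    for name in ("var_x1", "var_x2", "var_y1", "var_y2"):
        if getattr(params, name) <= 0:
            raise DomainError(f"{name} must be > 0")
    d1, d2 = params.delta1, params.delta2
    num = (1 - q) * params.cov_x + q * params.cov_y + q * (1 - q) * d1 * d2
    v1 = (1 - q) * params.var_x1 + q * params.var_y1 + q * (1 - q) * d1**2
    v2 = (1 - q) * params.var_x2 + q * params.var_y2 + q * (1 - q) * d2**2
    return float(num / np.sqrt(v1 * v2))


def simulate_mixture(
    params: MixtureParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n iid (Z1, Z2) pairs from the mixture model; Monte-Carlo
    verifier for :func:`mixture_correlation`."""
    covx = np.array([[params.var_x1, params.cov_x], [params.cov_x, params.var_x2]])
    covy = np.array([[params.var_y1, params.cov_y], [params.cov_y, params.var_y2]])
    theta = rng.random(n) < params.p
    X = rng.multivariate_normal([0.0, 0.0], covx, size=n, method="cholesky")
    Y = rng.multivariate_normal(
        [params.delta1, params.delta2], covy, size=n, method="cholesky"
    )
    Z = np.where(theta[:, None], Y, X)
    return Z[:, 0], Z[:, 1]


def adjacency(sim: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Elementwise soft threshold a_ij = s_ij**beta; diagonal zeroed so that
    row sums give connectivity."""
    if beta < 1:
        raise DomainError(f"beta must be >= 1, got {beta}")
    a = sim.s.astype(float) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(list(sim.gene_ids), a, int(beta))


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, pd.DataFrame]:
    """Signed scale-free fit index.

    Bin connectivity into equal-width bins, regress log10(frequency) on
    log10(mean k) over non-empty bins, and return (sign-of-slope folded)
    squared correlation plus the binned table.
    """
    kmax, kmin = k.max(), k.min()
    if kmax <= 0:
        raise DegenerateDataError("all-zero connectivity")
    edges = np.linspace(kmin, kmax, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.full(n_bins, np.nan)
    freq = np.zeros(n_bins)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k[b] = k[mask].mean()
            freq[b] = mask.mean()
    keep = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    table = pd.DataFrame({"mean_k": mean_k[keep], "frequency": freq[keep]})
    if keep.sum() < 3:
        raise DegenerateDataError(
            f"only {int(keep.sum())} non-empty connectivity bins; cannot assess scale-free fit"
        )
    lx = np.log10(table["mean_k"].to_numpy())
    ly = np.log10(table["frequency"].to_numpy())
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DegenerateDataError("degenerate log-log regression (constant axis)")
    r = np.corrcoef(lx, ly)[0, 1]
    slope = r * ly.std(ddof=1) / lx.std(ddof=1)
    return float(-np.sign(slope) * r**2), table


def _first_peak(r2: np.ndarray, beta_grid: list[int], r2_floor: float = 0.90) -> int:
    """First strict local maximum of r2 over the grid (peaks must point in
    the scale-free direction, r2 > 0); fall back to the smallest beta with
    r2 >= r2_floor, then to the grid argmax (warning)."""
    n = len(r2)
    for i in range(n):
        if r2[i] <= 0:
            continue
        left_ok = i == 0 or r2[i] > r2[i - 1]
        right_ok = i == n - 1 or r2[i] > r2[i + 1]
        if left_ok and right_ok:
            return beta_grid[i]
    for i in range(n):
        if r2[i] >= r2_floor:
            return beta_grid[i]
    warnings.warn("no first peak and no beta with r2 >= floor; using grid argmax")
    return beta_grid[int(np.argmax(r2))]


def scale_free_scan(
    sim: SimilarityMatrix,
    beta_grid: list[int] | None = None,
    n_bins: int = 10,
) -> ScaleFreeScan:
    """Scan soft-threshold powers and pick the first peak of the signed
    scale-free fit index."""
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    beta_grid = sorted(int(b) for b in beta_grid)
    if not beta_grid:
        raise DomainError("empty beta grid")
    if beta_grid[0] < 1:
        raise DomainError("beta grid must start at >= 1")
    if n_bins < 5:
        raise DomainError("n_bins must be >= 5")
    r2s, mean_ks = [], []
    for b in beta_grid:
        adj = adjacency(sim, b)
        k = adj.connectivity()
        fit, _ = _scale_free_fit(k, n_bins)
        r2s.append(fit)
        mean_ks.append(float(k.mean()))
    r2s_arr = np.asarray(r2s)
    chosen = _first_peak(r2s_arr, beta_grid)
    adj = adjacency(sim, chosen)
    k = adj.connectivity()
    _, table = _scale_free_fit(k, n_bins)
    return ScaleFreeScan(
        beta_grid=beta_grid,
        r2=r2s_arr,
        mean_connectivity=np.asarray(mean_ks),
        chosen_beta=chosen,
        k=k,
        pk_bins=table,
    )


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap.

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (the sum excludes u in {i, j}, which the zero diagonal already
    guarantees), tom_ii = 1.
    """
    a = adj.a
    if not np.allclose(np.diag(a), 0.0):
        raise DomainError("adjacency diagonal must be zero for TOM")
    k = a.sum(axis=1)
    shared = a @ a                       # diag(a)=0 makes this the u∉{i,j} sum
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(list(adj.gene_ids), t)
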