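"""Paired-design association of module eigengenes and single genes with
condition via a random-intercept linear mixed-effects model.

Model (per response y, one pair of observations per subject):

    y_ij = b_i + beta1 * condition_ij + beta_cov' c_i + e_ij
    b_i ~ N(beta0, tau^2),  e_ij ~ N(0, sigma^2),  independent

with subject-level covariates c_i constant within a pair.  For this balanced
two-observations-per-subject layout the REML likelihood factorises exactly
into the within-pair differences (which carry beta1 and sigma^2) and the
pair means (which carry the intercept, covariates and tau^2 + sigma^2/2),
so the fit is closed-form — no iterative optimisation:

* differences d_i = y_case - y_control ~ N(beta1, 2 sigma^2)
* means m_i ~ N(beta0 + beta1/2 + c_i' beta_cov, tau^2 + sigma^2/2)

When the implied tau^2 estimate is negative the fit is pinned to the
tau = 0 boundary (flagged) and sigma^2 is re-estimated by pooling both
factors, which is the constrained REML solution.

The Wald statistic for beta1 uses containment degrees of freedom
df = n_pairs - 1, which makes the no-covariate case numerically identical
to the classical paired t-test.

Gene significance (GS) of a gene is |t| from this model; module
significance (MS) is the mean GS over a module's genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, PairedDesign
from .errors import ConvergenceError, InsufficientDataError, ValidationError
from .modules import Eigengenes, ModuleSet, module_membership

__all__ = [
    "AssociationResult",
    "GeneStats",
    "fit_paired_lmm",
    "module_trait_table",
    "gene_significance",
    "gene_stats_frame",
    "module_significance",
    "mm_gs_scatter_table",
    "bh_fdr",
]


@dataclass
class AssociationResult:
    """Fixed-effect inference for the condition coefficient beta1."""

    estimate: float
    se: float
    statistic: float
    df: int
    p_value: float
    random_intercept_sd: float   # tau
    residual_sd: float           # sigma
    converged: bool = True
    boundary: bool = False       # tau estimate pinned at 0
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class GeneStats:
    gene_id: str
    gs: float                    # |t|
    gs_signed: float             # t
    p_value: float
    estimate: float
    module: str | None = None
    mm: float | None = None
    error: str | None = None     # set when the per-gene fit failed


def _paired_layout(design: PairedDesign) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (pair order, control sample index, case sample index) into the
    design's sample order."""
    pos = {s: i for i, s in enumerate(design.sample_ids)}
    by_pair: dict[str, dict[int, str]] = {}
    for s, p, c in zip(design.sample_ids, design.pair_ids, design.conditions):
        by_pair.setdefault(p, {})[int(c)] = s
    pairs = sorted(by_pair)
    ctrl = np.array([pos[by_pair[p][0]] for p in pairs])
    case = np.array([pos[by_pair[p][1]] for p in pairs])
    return pairs, ctrl, case


def _covariate_matrix(
    design: PairedDesign,
    pairs: list[str],
    ctrl_idx: np.ndarray,
    covariates: list[str] | None,
    stage_coding: str = "numeric",
) -> tuple[np.ndarray, list[str]]:
    """Subject-level covariate columns, one row per pair (taken from the
    control sample; the design invariant guarantees within-pair equality)."""
    if not covariates:
        return np.empty((len(pairs), 0)), []
    missing = [c for c in covariates if c not in design.covariates.columns]
    if missing:
        raise ValidationError(f"covariates not in design: {missing}")
    cov = design.covariates.iloc[ctrl_idx][covariates].copy()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in covariates:
        col = cov[c]
        if c == "stage" and stage_coding == "categorical":
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
                names.append(f"stage[{lev}]")
        else:
            cols.append(pd.to_numeric(col).to_numpy(float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(pairs), 0))
    return X, names


def fit_paired_lmm(
    response: np.ndarray,
    design: PairedDesign,
    covariates: list[str] | None = None,
    stage_coding: str = "numeric",
) -> AssociationResult:
    """REML fit of the random-intercept model for one response vector.

    ``response`` must be aligned with ``design.sample_ids``.  Requires at
    least 3 complete pairs.  Subject-level covariates enter the mean model
    only; the condition effect is inferred with df = n_pairs - 1.
    """
    y = np.asarray(response, dtype=float)
    if y.shape != (len(design.sample_ids),):
        raise ValidationError(
            f"response length {y.shape} does not match {len(design.sample_ids)} design samples"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite response values")
    pairs, ctrl, case = _paired_layout(design)
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {n}")
    Xc, cov_names = _covariate_matrix(design, pairs, ctrl, covariates, stage_coding)
    q = 1 + Xc.shape[1]
    if n - q < 1:
        raise InsufficientDataError(f"{n} pairs cannot support {q} mean-model parameters")

    d = y[case] - y[ctrl]                        # carries beta1 and sigma^2
    m = (y[case] + y[ctrl]) / 2.0                # carries covariates and tau^2

    beta1 = float(d.mean())
    ss_d = float(np.sum((d - beta1) ** 2))
    sigma2 = ss_d / (2.0 * (n - 1))

    # mean model: m ~ 1 + covariates
    Xm = np.column_stack([np.ones(n), Xc])
    coef, _, rank, _ = np.linalg.lstsq(Xm, m, rcond=None)
    if rank < Xm.shape[1]:
        raise ConvergenceError(
            f"singular mean-model design (rank {rank} < {Xm.shape[1]}); "
            f"covariates {cov_names} are collinear or constant"
        )
    resid_m = m - Xm @ coef
    rss_m = float(resid_m @ resid_m)
    omega2 = rss_m / (n - q)                     # tau^2 + sigma^2 / 2

    boundary = omega2 < sigma2 / 2.0
    if boundary:
        # constrained REML at tau = 0: pool both variance factors
        sigma2 = (ss_d / 2.0 + 2.0 * rss_m) / ((n - 1) + (n - q))
        tau2 = 0.0
    else:
        tau2 = omega2 - sigma2 / 2.0

    se = float(np.sqrt(2.0 * sigma2 / n))
    df = n - 1
    if se > 0:
        tstat = beta1 / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
    else:
        tstat = 0.0 if beta1 == 0 else np.inf * np.sign(beta1)
        p = 1.0 if beta1 == 0 else 0.0

    cov_effects: dict[str, dict[str, float]] = {}
    if cov_names:
        XtX_inv = np.linalg.inv(Xm.T @ Xm)
        for j, name in enumerate(cov_names, start=1):
            se_j = float(np.sqrt(max(omega2, sigma2 / 2.0) * XtX_inv[j, j]))
            est_j = float(coef[j])
            t_j = est_j / se_j if se_j > 0 else 0.0
            p_j = 2.0 * stats.t.sf(abs(t_j), n - q)
            cov_effects[name] = {"estimate": est_j, "se": se_j, "t": t_j, "p": p_j}

    return AssociationResult(
        estimate=beta1,
        se=se,
        statistic=float(tstat),
        df=df,
        p_value=float(p),
        random_intercept_sd=float(np.sqrt(tau2)),
        residual_sd=float(np.sqrt(sigma2)),
        converged=True,
        boundary=bool(boundary),
        covariate_effects=cov_effects,
    )


def module_trait_table(
    eig: Eigengenes,
    design: PairedDesign,
    covariates: list[str] | None = None,
    stage_coding: str = "numeric",
) -> pd.DataFrame:
    """One condition-association row per module eigengene (grey included),
    ordered by |t| descending.  Per-module failures are recorded, not fatal.
    """
    missing = sorted(set(design.sample_ids) - set(eig.sample_ids))
    if missing:
        raise ValidationError(f"design samples without eigengene values: {missing}")
    pos = {s: i for i, s in enumerate(eig.sample_ids)}
    order = [pos[s] for s in design.sample_ids]
    rows = []
    for lab, me in eig.me.items():
        try:
            res = fit_paired_lmm(me[order], design, covariates, stage_coding)
            rows.append(
                dict(module=lab, estimate=res.estimate, se=res.se, t=res.statistic,
                     df=res.df, p=res.p_value, tau=res.random_intercept_sd,
                     sigma=res.residual_sd, boundary=res.boundary, error="")
            )
        except Exception as exc:  # noqa: BLE001 - recorded per module
            rows.append(
                dict(module=lab, estimate=np.nan, se=np.nan, t=np.nan, df=0,
                     p=np.nan, tau=np.nan, sigma=np.nan, boundary=False, error=str(exc))
            )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df.loc[ok, "fdr"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df = df.sort_values("t", key=lambda s: s.abs(), ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def gene_significance(
    expr: ExpressionMatrix,
    design: PairedDesign,
    covariates: list[str] | None = None,
    stage_coding: str = "numeric",
) -> list[GeneStats]:
    """Per-gene LMM condition test; GS = |t|, ordered by gene id.

    Per-gene failures are recorded on the GeneStats entry (gs = nan) and do
    not stop the scan.
    """
    design.check_against(expr)
    sub = expr.subset_samples(design.sample_ids)
    out: list[GeneStats] = []
    for gi in sorted(range(sub.n_genes), key=lambda i: sub.gene_ids[i]):
        g = sub.gene_ids[gi]
        try:
            res = fit_paired_lmm(sub.values[gi], design, covariates, stage_coding)
            out.append(GeneStats(g, abs(res.statistic), res.statistic,
                                 res.p_value, res.estimate))
        except Exception as exc:  # noqa: BLE001 - recorded per gene
            out.append(GeneStats(g, np.nan, np.nan, np.nan, np.nan, error=str(exc)))
    return out


def gene_stats_frame(
    genestats: list[GeneStats],
    modset: ModuleSet | None = None,
    expr: ExpressionMatrix | None = None,
    eig: Eigengenes | None = None,
) -> pd.DataFrame:
    """Tabulate GeneStats; optionally annotate module and module membership.

    Adds gs_scaled = gs / max(gs) (the |t| scale is kept as the primary GS;
    the scaled column is a convenience for cross-study comparison) and BH
    FDR over the valid fits.
    """
    rows = []
    for st in genestats:
        module = st.module
        mm = st.mm
        if modset is not None:
            module = modset.assignment.get(st.gene_id, module)
        if mm is None and expr is not None and eig is not None and module in (eig.me or {}):
            try:
                mm = module_membership(expr, eig, st.gene_id, module)
            except ValidationError:
                mm = np.nan
        rows.append(dict(gene_id=st.gene_id, module=module, estimate=st.estimate,
                         gs_signed=st.gs_signed, gs=st.gs, mm=mm,
                         p=st.p_value, error=st.error or ""))
    df = pd.DataFrame(rows)
    gmax = df["gs"].max()
    df["gs_scaled"] = df["gs"] / gmax if gmax and np.isfinite(gmax) and gmax > 0 else np.nan
    ok = df["p"].notna()
    df.loc[ok, "fdr"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    return df


def module_significance(genestats: list[GeneStats], modset: ModuleSet) -> pd.DataFrame:
    """MS per module = arithmetic mean GS over the module's genes with valid
    fits; modules with zero valid fits get a missing MS."""
    gs_of = {st.gene_id: st.gs for st in genestats}
    missing = [g for g in modset.assignment if g not in gs_of]
    if missing:
        raise ValidationError(f"genes without a GeneStats entry: {missing[:5]}...")
    rows = []
    for lab in modset.all_labels():
        genes = modset.genes_in(lab)
        vals = np.array([gs_of[g] for g in genes], dtype=float)
        vals = vals[np.isfinite(vals)]
        rows.append(dict(module=lab, n_genes=len(genes), n_valid=len(vals),
                         ms=float(vals.mean()) if len(vals) else np.nan))
    return pd.DataFrame(rows)


def mm_gs_scatter_table(
    expr: ExpressionMatrix,
    genestats: list[GeneStats],
    modset: ModuleSet,
    eig: Eigengenes,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene (|MM|, GS) pairs within each module plus the per-module
    Pearson correlation of |MM| vs GS (needs >= 3 genes with valid fits)."""
    per_gene = gene_stats_frame(genestats, modset, expr, eig)
    per_gene = per_gene[per_gene["module"].notna()].copy()
    per_gene["abs_mm"] = per_gene["mm"].abs()
    rows = []
    for lab, grp in per_gene.groupby("module", sort=False):
        g = grp.dropna(subset=["abs_mm", "gs"])
        if len(g) >= 3 and g["abs_mm"].std() > 0 and g["gs"].std() > 0:
            r = float(np.corrcoef(g["abs_mm"], g["gs"])[0, 1])
        else:
            r = np.nan
        rows.append(dict(module=lab, n=len(g), cor_mm_gs=r))
    return per_gene[["gene_id", "module", "abs_mm", "gs"]], pd.DataFrame(rows)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
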