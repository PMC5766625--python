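"""Synthetic paired two-condition expression data with planted co-expression
modules, per-pair random intercepts, and condition mean shifts.

Generative model per gene g in planted module m and sample s (subject i,
condition c):

    x_gs = loading_g * z_ms + b_gi + c * loading_g * shift_m + eps_gs

with latent module score z_ms ~ N(0,1) drawn independently per sample
(group-centred so the score itself carries no case/control mean
difference), gene-specific pair intercept b_gi ~ N(0, pair_sd^2) (the
random intercept of the per-response mixed model — each gene carries its
own, so the pair effect does not induce spurious between-gene
correlation), and noise eps ~ N(0, residual_sd^2).  The condition shift
enters each gene's mean scaled by its loading: strongly loaded genes carry
more of the module's condition effect, which is what couples module
membership to gene significance.  Noise genes have no latent score and no
shift.  ``shift`` is specified in units of the residual SD.  Optional
subject-level covariates (age, stage) can be given linear effects shared
by all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data_io import ExpressionMatrix, PairedDesign
from .errors import ValidationError
from .modules import GREY, ModuleSet

__all__ = ["ModuleSpec", "SimConfig", "SimTruth", "simulate",
           "default_config", "recover_and_score"]

NOISE = "noise"


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    loading_mean: float          # in (0, 1]
    condition_shift: float       # in residual-SD units


@dataclass
class SimConfig:
    n_pairs: int = 38
    modules: tuple[ModuleSpec, ...] = ()
    n_noise_genes: int = 300
    pair_sd: float = 1.0
    residual_sd: float = 1.0
    loading_spread: float = 0.2  # loadings ~ U(mean-spread, mean+spread) clipped to (0.05, 1]
    covariate_effects: dict[str, float] | None = None  # e.g. {"age": 0.01, "stage": 0.1}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValidationError("n_pairs must be >= 3")
        if any(m.size < 1 for m in self.modules):
            raise ValidationError("module sizes must be >= 1")
        if any(not 0 < m.loading_mean <= 1 for m in self.modules):
            raise ValidationError("loading_mean must be in (0, 1]")
        if self.pair_sd <= 0 or self.residual_sd <= 0:
            raise ValidationError("pair_sd and residual_sd must be > 0")


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale scenario: 38 pairs; planted modules of sizes 250/190/80
    with decreasing condition shifts; 300 noise genes.

    Variance components are set so that within-module pooled correlations
    sit around 0.5 — strong but noisy co-expression, comparable to what a
    soft power of ~6 resolves cleanly.
    """
    return SimConfig(
        n_pairs=38,
        modules=(
            ModuleSpec(size=250, loading_mean=0.8, condition_shift=1.0),
            ModuleSpec(size=190, loading_mean=0.8, condition_shift=0.5),
            ModuleSpec(size=80, loading_mean=0.8, condition_shift=0.0),
        ),
        n_noise_genes=300,
        pair_sd=0.5,
        residual_sd=0.5,
        seed=seed,
    )


@dataclass
class SimTruth:
    module_of: dict[str, str]          # gene -> planted module id ("M1".. / "noise")
    loading: dict[str, float]
    shift: dict[str, float]            # on the expression scale
    pair_intercepts: pd.DataFrame      # genes x pairs random intercepts
    module_ids: list[str] = field(default_factory=list)

    def labels_for(self, gene_ids: list[str]) -> list[str]:
        return [self.module_of[g] for g in gene_ids]


def simulate(config: SimConfig) -> tuple[ExpressionMatrix, PairedDesign, SimTruth]:
    """Generate (expression, design, truth); bitwise reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_pairs
    n_samples = 2 * n_pairs
    width = max(2, len(str(n_pairs)))
    pair_ids_u = [f"P{i + 1:0{width}d}" for i in range(n_pairs)]
    sample_ids = [f"{p}_{suffix}" for p in pair_ids_u for suffix in ("ctl", "tum")]
    pair_per_sample = [p for p in pair_ids_u for _ in range(2)]
    condition = np.tile([0, 1], n_pairs)

    age = rng.integers(30, 80, size=n_pairs).astype(float)
    stage = rng.integers(1, 5, size=n_pairs).astype(float)
    covariates = pd.DataFrame(
        {"age": np.repeat(age, 2), "stage": np.repeat(stage, 2)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cov_term = np.zeros(n_samples)
    if config.covariate_effects:
        for name, beta in config.covariate_effects.items():
            cov_term = cov_term + beta * covariates[name].to_numpy()

    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    loading: dict[str, float] = {}
    shift: dict[str, float] = {}
    blocks: list[np.ndarray] = []
    intercept_blocks: list[np.ndarray] = []
    module_ids: list[str] = []
    for mi, mspec in enumerate(config.modules, start=1):
        mid = f"M{mi}"
        module_ids.append(mid)
        z = rng.normal(0.0, 1.0, size=n_samples)       # latent module score per sample
        # the score itself carries no case/control mean difference: any
        # condition effect enters through the explicit shift term only
        z[condition == 0] -= z[condition == 0].mean()
        z[condition == 1] -= z[condition == 1].mean()
        lo = max(0.05, mspec.loading_mean - config.loading_spread)
        hi = min(1.0, mspec.loading_mean + config.loading_spread)
        loads = rng.uniform(lo, hi, size=mspec.size)
        delta_g = loads * mspec.condition_shift * config.residual_sd
        b = rng.normal(0.0, config.pair_sd, size=(mspec.size, n_pairs))
        eps = rng.normal(0.0, config.residual_sd, size=(mspec.size, n_samples))
        block = (loads[:, None] * z[None, :] + np.repeat(b, 2, axis=1)
                 + delta_g[:, None] * condition[None, :] + cov_term[None, :] + eps)
        blocks.append(block)
        intercept_blocks.append(b)
        for gi in range(mspec.size):
            g = f"{mid}_g{gi + 1:04d}"
            gene_ids.append(g)
            module_of[g] = mid
            loading[g] = float(loads[gi])
            shift[g] = float(delta_g[gi])
    if config.n_noise_genes:
        b = rng.normal(0.0, config.pair_sd, size=(config.n_noise_genes, n_pairs))
        eps = rng.normal(0.0, config.residual_sd, size=(config.n_noise_genes, n_samples))
        block = np.repeat(b, 2, axis=1) + cov_term[None, :] + eps
        blocks.append(block)
        intercept_blocks.append(b)
        for gi in range(config.n_noise_genes):
            g = f"noise_g{gi + 1:04d}"
            gene_ids.append(g)
            module_of[g] = NOISE
            loading[g] = 0.0
            shift[g] = 0.0

    values = np.vstack(blocks) if blocks else np.empty((0, n_samples))
    intercepts = (np.vstack(intercept_blocks) if intercept_blocks
                  else np.empty((0, n_pairs)))
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    design = PairedDesign(sample_ids, pair_per_sample, condition, covariates)
    truth = SimTruth(
        module_of=module_of, loading=loading, shift=shift,
        pair_intercepts=pd.DataFrame(intercepts, index=gene_ids, columns=pair_ids_u),
        module_ids=module_ids,
    )
    return expr, design, truth


def _match_modules(truth: SimTruth, modset: ModuleSet, gene_ids: list[str]) -> dict[str, str]:
    """Greedy max-overlap matching planted module id -> detected label."""
    overlap: dict[tuple[str, str], int] = {}
    for g in gene_ids:
        t = truth.module_of[g]
        d = modset.assignment[g]
        if t != NOISE and d != GREY:
            overlap[(t, d)] = overlap.get((t, d), 0) + 1
    matched: dict[str, str] = {}
    used: set[str] = set()
    for (t, d), _ in sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0])):
        if t not in matched and d not in used:
            matched[t] = d
            used.add(d)
    return matched


def recover_and_score(
    expr: ExpressionMatrix,
    truth: SimTruth,
    modset: ModuleSet,
    shift_estimates: dict[str, float] | None = None,
    hubs: dict[str, str] | None = None,
) -> dict:
    """Score pipeline output against the planted truth.

    Returns ARI between planted and detected partitions (noise genes and
    grey treated as the same background class), the planted->detected module
    matching, per-module shift-estimate bias (when per-detected-module
    estimates are supplied), and hub hit flags (hub == max-loading gene of
    the matched planted module).
    """
    genes = expr.gene_ids
    missing = [g for g in genes if g not in modset.assignment]
    if missing:
        raise ValidationError(f"genes without module assignment: {missing[:5]}")
    t_labels = ["__bg__" if truth.module_of[g] == NOISE else truth.module_of[g] for g in genes]
    d_labels = ["__bg__" if modset.assignment[g] == GREY else modset.assignment[g] for g in genes]
    ari = float(adjusted_rand_score(t_labels, d_labels))
    matching = _match_modules(truth, modset, genes)
    out: dict = {"ari": ari, "matching": matching,
                 "n_detected_modules": len(modset.labels),
                 "n_planted_modules": len(truth.module_ids)}
    if shift_estimates is not None:
        bias = {}
        for t, d in matching.items():
            if d in shift_estimates:
                planted = np.mean([truth.shift[g] for g, m in truth.module_of.items() if m == t])
                bias[t] = float(shift_estimates[d] - planted)
        out["shift_bias"] = bias
    if hubs is not None:
        hits = {}
        for t, d in matching.items():
            if d in hubs:
                module_genes = [g for g, m in truth.module_of.items() if m == t]
                best = max(module_genes, key=lambda g: truth.loading[g])
                hits[t] = bool(hubs[d] == best)
        out["hub_hits"] = hits
    return out
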