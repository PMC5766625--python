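import numpy as np
import pandas as pd
import pytest

from pairedwgcna import (ExpressionMatrix, PairedDesign, ModuleSpec, SimConfig,
                         simulate)


def make_design(n_pairs: int, seed: int = 0, with_covariates: bool = True) -> PairedDesign:
    rng = np.random.default_rng(seed)
    sample_ids = [f"P{i:02d}_{s}" for i in range(n_pairs) for s in ("c", "t")]
    pair_ids = [f"P{i:02d}" for i in range(n_pairs) for _ in range(2)]
    conditions = np.tile([0, 1], n_pairs)
    cov = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    if with_covariates:
        age = np.repeat(rng.integers(30, 80, n_pairs).astype(float), 2)
        stage = np.repeat(rng.integers(1, 5, n_pairs).astype(float), 2)
        cov = pd.DataFrame({"age": age, "stage": stage},
                           index=pd.Index(sample_ids, name="sample_id"))
    return PairedDesign(sample_ids, pair_ids, conditions, cov)


def random_expr(n_genes: int, n_samples: int, seed: int = 0,
                sample_ids=None) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, rng.normal(0, 1, (n_genes, n_samples)))


@pytest.fixture
def design8():
    return make_design(8, seed=1)


@pytest.fixture(scope="session")
def sim_small():
    """Small planted-module dataset shared by module/hub tests."""
    cfg = SimConfig(
        n_pairs=20,
        modules=(ModuleSpec(40, 0.8, 1.0), ModuleSpec(30, 0.8, 0.0)),
        n_noise_genes=50,
        pair_sd=0.5,
        residual_sd=0.5,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_default():
    """Study-scale scenario (38 pairs; 250/190/80 planted; 300 noise)."""
    from pairedwgcna import default_config

    return simulate(default_config(seed=5))
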