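import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairedwgcna import (ExpressionMatrix, GREY, ModuleSet, bh_fdr,
                         compute_eigengenes, fit_paired_lmm, gene_significance,
                         gene_stats_frame, mm_gs_scatter_table,
                         module_significance, module_trait_table)
from pairedwgcna.errors import InsufficientDataError, ValidationError
from pairedwgcna.modules import Eigengenes

from conftest import make_design, random_expr


def paired_t(y, design):
    """Classical paired t-test oracle."""
    d = {}
    for s, p, c in zip(design.sample_ids, design.pair_ids, design.conditions):
        d.setdefault(p, {})[c] = y[design.sample_ids.index(s)]
    diffs = np.array([d[p][1] - d[p][0] for p in sorted(d)])
    t, pv = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(pv), len(diffs) - 1


class TestFitPairedLMM:
    def test_paired_t_equivalence(self):
        rng = np.random.default_rng(0)
        design = make_design(15, seed=0)
        for rep in range(20):
            y = (np.repeat(rng.normal(0, 1.2, 15), 2)
                 + 0.4 * design.conditions + rng.normal(0, 1, 30))
            res = fit_paired_lmm(y, design)
            t, pv, df = paired_t(y, design)
            assert res.statistic == pytest.approx(t, abs=1e-8)
            assert res.p_value == pytest.approx(pv, abs=1e-8)
            assert res.df == df == 14

    def test_matches_statsmodels_reml(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        design = make_design(20, seed=7)
        y = (np.repeat(rng.normal(0, 1.5, 20), 2) + 0.8 * design.conditions
             + 0.01 * design.covariates["age"].to_numpy() + rng.normal(0, 1, 40))
        mine = fit_paired_lmm(y, design, ["age"])
        df = pd.DataFrame({"y": y, "cond": design.conditions,
                           "age": design.covariates["age"].to_numpy(),
                           "pair": design.pair_ids})
        sm_fit = smf.mixedlm("y ~ cond + age", df, groups=df["pair"]).fit(reml=True)
        assert mine.estimate == pytest.approx(sm_fit.params["cond"], abs=1e-6)
        assert mine.se == pytest.approx(sm_fit.bse["cond"], rel=1e-3)
        assert mine.random_intercept_sd**2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert mine.residual_sd**2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_zero_differences(self):
        design = make_design(5)
        y = np.repeat(np.arange(5.0), 2)  # identical within every pair
        res = fit_paired_lmm(y, design)
        assert res.estimate == 0.0 and res.statistic == 0.0
        assert res.p_value == 1.0

    def test_boundary_flag(self):
        # pair means exactly constant -> tau estimate pinned at 0
        design = make_design(6)
        rng = np.random.default_rng(1)
        half = rng.normal(0, 1, 6)
        y = np.empty(12)
        y[design.conditions == 0] = -half
        y[design.conditions == 1] = half
        res = fit_paired_lmm(y, design)
        assert res.boundary
        assert res.random_intercept_sd == 0.0
        assert res.converged

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        design = make_design(10, seed=2)
        y = np.repeat(rng.normal(0, 1, 10), 2) + 0.5 * design.conditions \
            + rng.normal(0, 1, 20)
        flipped = type(design)(design.sample_ids, design.pair_ids,
                               1 - design.conditions, design.covariates)
        r1 = fit_paired_lmm(y, design)
        r2 = fit_paired_lmm(y, flipped)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-10)

    def test_covariates_leave_condition_test_unchanged(self):
        # subject-level covariates are orthogonal to the within-pair contrast
        rng = np.random.default_rng(3)
        design = make_design(12, seed=3)
        y = np.repeat(rng.normal(0, 1, 12), 2) + 0.3 * design.conditions \
            + rng.normal(0, 1, 24)
        r0 = fit_paired_lmm(y, design)
        r1 = fit_paired_lmm(y, design, ["age", "stage"])
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-12)
        assert r1.statistic == pytest.approx(r0.statistic, abs=1e-12)
        assert r1.df == r0.df
        assert set(r1.covariate_effects) == {"age", "stage"}

    def test_categorical_stage(self):
        design = make_design(12, seed=4)
        rng = np.random.default_rng(4)
        y = np.repeat(rng.normal(0, 1, 12), 2) + rng.normal(0, 1, 24)
        res = fit_paired_lmm(y, design, ["stage"], stage_coding="categorical")
        assert any(k.startswith("stage[") for k in res.covariate_effects)

    def test_too_few_pairs(self):
        design = make_design(3)
        sub = design.subset([s for s, p in zip(design.sample_ids, design.pair_ids)
                             if p in ("P00", "P01")])
        with pytest.raises(InsufficientDataError):
            fit_paired_lmm(np.arange(4.0), sub)

    def test_response_length_checked(self):
        design = make_design(5)
        with pytest.raises(ValidationError):
            fit_paired_lmm(np.arange(9.0), design)

    def test_type_one_error_quick(self):
        # null: pair effects only; nominal alpha 0.05
        rng = np.random.default_rng(5)
        design = make_design(20, seed=5)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            y = np.repeat(rng.normal(0, 1, 20), 2) + rng.normal(0, 1, 40)
            if fit_paired_lmm(y, design).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_power_one_within_pair_sd(self):
        # planted condition shift of 1 within-pair SD, 38 pairs
        rng = np.random.default_rng(6)
        design = make_design(38, seed=6)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = (np.repeat(rng.normal(0, 1, 38), 2) + 1.0 * design.conditions
                 + rng.normal(0, 1, 76))
            if fit_paired_lmm(y, design).p_value < 0.05:
                hits += 1
        assert hits / n_rep > 0.9


class TestModuleTraitTable:
    def test_ordering_and_sign_flip(self):
        rng = np.random.default_rng(8)
        design = make_design(20, seed=8)
        strong = rng.normal(0, 1, 40) + 2.0 * design.conditions
        weak = rng.normal(0, 1, 40)
        eig = Eigengenes(design.sample_ids,
                         {"turquoise": strong, "blue": weak},
                         {"turquoise": 0.5, "blue": 0.5})
        tab = module_trait_table(eig, design)
        assert tab.iloc[0]["module"] == "turquoise"
        assert abs(tab.iloc[0]["t"]) >= abs(tab.iloc[1]["t"])
        flipped = type(design)(design.sample_ids, design.pair_ids,
                               1 - design.conditions, design.covariates)
        tab2 = module_trait_table(eig, flipped)
        t1 = tab.set_index("module")["t"]
        t2 = tab2.set_index("module")["t"]
        np.testing.assert_allclose(t1, -t2, atol=1e-10)

    def test_null_me_type_one(self):
        # ME = pure pair effect: rejection rate near alpha over repetitions
        rng = np.random.default_rng(9)
        design = make_design(20, seed=9)
        n_rep = 500
        rej = 0
        for _ in range(n_rep):
            me = np.repeat(rng.normal(0, 1, 20), 2) + rng.normal(0, 0.7, 40)
            eig = Eigengenes(design.sample_ids, {"m": me}, {"m": 1.0})
            tab = module_trait_table(eig, design)
            rej += int(tab.iloc[0]["p"] < 0.05)
        assert 0.03 <= rej / n_rep <= 0.07


class TestGeneSignificance:
    def test_constant_within_pairs_zero_gs(self):
        design = make_design(5)
        V = np.vstack([np.repeat(np.arange(5.0), 2),
                       np.random.default_rng(0).normal(0, 1, 10)])
        m = ExpressionMatrix(["gA", "gB"], design.sample_ids, V)
        gs = gene_significance(m, design)
        by_id = {s.gene_id: s for s in gs}
        assert by_id["gA"].gs == 0.0

    def test_equals_abs_paired_t(self):
        # genes carry real pair effects so tau is estimated in the interior
        # (at the tau=0 boundary the REML fit deliberately pools variances
        # and is no longer the paired t - see fit_paired_lmm docs)
        rng = np.random.default_rng(10)
        design = make_design(12, seed=10)
        V = np.vstack([np.repeat(rng.normal(0, 1.5, 12), 2) + rng.normal(0, 1, 24)
                       for _ in range(6)])
        m = ExpressionMatrix([f"g{i:03d}" for i in range(6)],
                             design.sample_ids, V)
        stats_list = gene_significance(m, design)
        for st in stats_list:
            y = m.values[m.gene_ids.index(st.gene_id)]
            t, _, _ = paired_t(y, design)
            assert st.gs == pytest.approx(abs(t), abs=1e-8)
            assert st.gs_signed == pytest.approx(t, abs=1e-8)

    def test_ordering_by_gene_id(self):
        design = make_design(5, seed=11)
        m = random_expr(5, 10, seed=11, sample_ids=design.sample_ids)
        gs = gene_significance(m, design)
        ids = [s.gene_id for s in gs]
        assert ids == sorted(ids)

    def test_affine_invariance(self):
        design = make_design(10, seed=12)
        m = random_expr(4, 20, seed=12, sample_ids=design.sample_ids)
        gs1 = gene_significance(m, design)
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, 3.7 * m.values - 11.0)
        gs2 = gene_significance(m2, design)
        for a, b in zip(gs1, gs2):
            assert a.gs == pytest.approx(b.gs, abs=1e-9)

    def test_within_pair_permutation_destroys_signal(self):
        rng = np.random.default_rng(13)
        design = make_design(30, seed=13)
        shift = 1.0
        V = np.vstack([np.repeat(rng.normal(0, 1, 30), 2)
                       + shift * design.conditions + rng.normal(0, 1, 60)
                       for _ in range(40)])
        m = ExpressionMatrix([f"g{i:02d}" for i in range(40)],
                             design.sample_ids, V)
        gs_obs = np.array([s.gs for s in gene_significance(m, design)])
        # permute condition labels within pairs
        flip = rng.random(30) < 0.5
        new_cond = design.conditions.copy()
        for i, p in enumerate(sorted(set(design.pair_ids))):
            if flip[i]:
                idx = [j for j, q in enumerate(design.pair_ids) if q == p]
                new_cond[idx] = 1 - new_cond[idx]
        permuted = type(design)(design.sample_ids, design.pair_ids, new_cond,
                                design.covariates)
        gs_perm = np.array([s.gs for s in gene_significance(m, permuted)])
        null_level = np.sqrt(2 / np.pi)  # E|t| for large df
        assert gs_obs.mean() > 2.0
        assert gs_perm.mean() < gs_obs.mean() / 2
        assert abs(gs_perm.mean() - null_level) < 0.5


class TestModuleSignificance:
    def _stats(self, vals):
        from pairedwgcna.association import GeneStats

        return [GeneStats(g, v, v, 0.5, 0.1) for g, v in vals.items()]

    def test_constant_gs(self):
        ms = ModuleSet({"a": "turquoise", "b": "turquoise", "c": GREY})
        tab = module_significance(self._stats({"a": 2.0, "b": 2.0, "c": 1.0}), ms)
        assert tab.set_index("module").loc["turquoise", "ms"] == 2.0

    def test_union_linearity(self):
        vals = {f"g{i}": float(i) for i in range(6)}
        ms_split = ModuleSet({"g0": "a", "g1": "a", "g2": "b", "g3": "b",
                              "g4": "b", "g5": "b"})
        ms_union = ModuleSet({g: "u" for g in vals})
        t_split = module_significance(self._stats(vals), ms_split).set_index("module")
        t_union = module_significance(self._stats(vals), ms_union).set_index("module")
        expected = (2 * t_split.loc["a", "ms"] + 4 * t_split.loc["b", "ms"]) / 6
        assert t_union.loc["u", "ms"] == pytest.approx(expected)

    def test_planted_module_highest_ms(self, sim_default):
        expr, design, truth = sim_default
        genestats = gene_significance(expr, design)
        ms = ModuleSet({g: truth.module_of[g] for g in expr.gene_ids})
        tab = module_significance(genestats, ms).set_index("module")
        assert tab["ms"].idxmax() == "M1"  # largest planted shift

    def test_missing_entry_rejected(self):
        ms = ModuleSet({"a": "turquoise", "b": "turquoise"})
        with pytest.raises(ValidationError):
            module_significance(self._stats({"a": 1.0}), ms)


class TestMMGS:
    def test_exact_linear_relation(self):
        from pairedwgcna.association import GeneStats

        rng = np.random.default_rng(14)
        design = make_design(10, seed=14)
        me = rng.normal(0, 1, 20)
        # genes = a*ME + orthogonal noise with controlled |MM| spread
        genes = []
        mms = [0.9, 0.7, 0.5, 0.3]
        for rho in mms:
            noise = rng.normal(0, 1, 20)
            noise -= (noise @ (me - me.mean())) / ((me - me.mean()) @ (me - me.mean())) \
                * (me - me.mean())
            mec = (me - me.mean()) / (me - me.mean()).std()
            nc = (noise - noise.mean()) / (noise - noise.mean()).std()
            genes.append(rho * mec + np.sqrt(1 - rho**2) * nc)
        m = ExpressionMatrix([f"g{i}" for i in range(4)], design.sample_ids,
                             np.vstack(genes))
        modset = ModuleSet({g: "turquoise" for g in m.gene_ids})
        eig = Eigengenes(design.sample_ids, {"turquoise": me}, {"turquoise": 1})
        # construct GS as exact linear function of |MM|
        stats_list = [GeneStats(f"g{i}", 2 * rho + 1, 2 * rho + 1, 0.1, 0.1)
                      for i, rho in enumerate(mms)]
        _, per_module = mm_gs_scatter_table(m, stats_list, modset, eig)
        r = per_module.set_index("module").loc["turquoise", "cor_mm_gs"]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_planted_module_positive_correlation(self):
        # associated module with heterogeneous loadings: GS grows with |MM|
        from pairedwgcna import ModuleSpec, SimConfig, simulate

        cfg = SimConfig(n_pairs=38, modules=(ModuleSpec(100, 0.6, 2.0),),
                        n_noise_genes=100, pair_sd=0.5, residual_sd=0.5,
                        loading_spread=0.4, seed=5)
        expr, design, truth = simulate(cfg)
        modset = ModuleSet({g: ("turquoise" if truth.module_of[g] == "M1"
                                else GREY) for g in expr.gene_ids})
        eig = compute_eigengenes(expr, modset, include_grey=False)
        genestats = gene_significance(expr, design)
        _, per_module = mm_gs_scatter_table(expr, genestats, modset, eig)
        r = per_module.set_index("module").loc["turquoise", "cor_mm_gs"]
        assert r > 0.5

    def test_tiny_module_missing_correlation(self):
        from pairedwgcna.association import GeneStats

        design = make_design(5, seed=15)
        m = random_expr(2, 10, seed=15, sample_ids=design.sample_ids)
        modset = ModuleSet({"g000": "turquoise", "g001": "turquoise"})
        eig = compute_eigengenes(m, modset, include_grey=False)
        stats_list = [GeneStats("g000", 1.0, 1.0, 0.5, 0.1),
                      GeneStats("g001", 2.0, 2.0, 0.5, 0.1)]
        _, per_module = mm_gs_scatter_table(m, stats_list, modset, eig)
        assert np.isnan(per_module.set_index("module").loc["turquoise", "cor_mm_gs"])


class TestFDR:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(16)
        p = rng.uniform(0, 1, 50)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_gene_stats_frame_columns(self, sim_small):
        expr, design, truth = sim_small
        modset = ModuleSet({g: truth.module_of[g] for g in expr.gene_ids})
        eig = compute_eigengenes(expr, modset, include_grey=False)
        gs = gene_significance(expr, design)
        frame = gene_stats_frame(gs, modset, expr, eig)
        assert {"gene_id", "module", "gs", "gs_signed", "gs_scaled",
                "mm", "p", "fdr"} <= set(frame.columns)
        assert frame["gs_scaled"].max() == pytest.approx(1.0)
        np.testing.assert_allclose(frame["gs"], frame["gs_signed"].abs())
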