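import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sexdiet import de_engine, synthdata
from sexdiet.de_engine import (
    DataError,
    UsageError,
    bh_adjust,
    build_design,
    estimate_dispersions,
    filter_low_expression,
    fit_nb_glm,
    lrt_term,
    per_sex_fold_changes,
    tmm_normalize,
)
from sexdiet.tables_io import CountMatrix


def _meta(n_reps):
    sexes = ["F"] * (2 * n_reps) + ["M"] * (2 * n_reps)
    diets = (["C"] * n_reps + ["P"] * n_reps) * 2
    ids = [f"{s}{d}{i}" for i, (s, d) in enumerate(zip(sexes, diets))]
    return pd.DataFrame({"sex": sexes, "diet": diets,
                         "replicate": list(range(1, n_reps + 1)) * 4},
                        index=pd.Index(ids, name="sample"))


# ---------------------------------------------------------------------------
# TMM


def tmm_oracle(arr, ref_idx, trim_m=0.30, trim_a=0.05):
    """Plain-Python step-by-step reimplementation of the trim-and-weight
    recipe, independent of the vectorized implementation."""
    lib = arr.sum(axis=0)
    log_factors = []
    for i in range(arr.shape[1]):
        obs, ref = arr[:, i], arr[:, ref_idx]
        m_vals, a_vals, w_vals = [], [], []
        for g in range(arr.shape[0]):
            if obs[g] > 0 and ref[g] > 0:
                po, pr = obs[g] / lib[i], ref[g] / lib[ref_idx]
                m_vals.append(np.log2(po / pr))
                a_vals.append(0.5 * np.log2(po * pr))
                w_vals.append((lib[i] - obs[g]) / (lib[i] * obs[g])
                              + (lib[ref_idx] - ref[g]) / (lib[ref_idx] * ref[g]))
        n = len(m_vals)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m_vals)
        rank_a = stats.rankdata(a_vals)
        num = den = 0.0
        for j in range(n):
            if lo_m <= rank_m[j] <= hi_m and lo_a <= rank_a[j] <= hi_a:
                num += m_vals[j] / w_vals[j]
                den += 1.0 / w_vals[j]
        log_factors.append(num / den if den else 0.0)
    f = 2.0 ** np.array(log_factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        arr = np.tile(np.arange(1, 101)[:, None], (1, 4))
        nf = tmm_normalize(arr)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_difference_absorbed_by_lib_size(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 500, size=100)
        arr = np.column_stack([a, 2 * a])
        nf = tmm_normalize(arr)
        assert np.allclose(nf.factors, 1.0)
        assert nf.lib_sizes[1] == 2 * nf.lib_sizes[0]

    def test_matches_independent_oracle(self):
        """Five 50-fold-inflated genes in one sample: factors agree with the
        step-by-step recipe to 1e-10."""
        rng = np.random.default_rng(1)
        arr = rng.integers(10, 1000, size=(100, 4)).astype(float)
        arr[:5, 2] *= 50
        nf = tmm_normalize(arr)
        lib = arr.sum(axis=0)
        q75 = np.quantile(arr / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
        assert np.allclose(nf.factors, tmm_oracle(arr, ref_idx), atol=1e-10)

    def test_geometric_mean_one_and_scaling_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.negative_binomial(5, 0.01, size=(200, 6)).astype(float) + 1
        nf = tmm_normalize(arr)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-8)
        nf2 = tmm_normalize(arr * 3)
        assert np.allclose(nf.factors, nf2.factors)

    def test_zero_library_rejected(self):
        arr = np.ones((10, 3))
        arr[:, 0] = 0
        with pytest.raises(DataError):
            tmm_normalize(arr)


class TestFilter:
    def test_zero_threshold_removes_only_all_zero_genes(self, small_sim):
        cm, _ = small_sim
        filtered = filter_low_expression(cm, cpm_threshold=0.0, min_samples=1)
        all_zero = (cm.counts.sum(axis=1) == 0)
        assert filtered.n_genes == (~all_zero).sum()

    def test_hand_computed_cpm_retention(self):
        # lib sizes 100 -> CPM = count * 1e4
        counts = pd.DataFrame({
            "FC1": [60, 20, 10, 10], "FP1": [60, 25, 10, 5],
            "MC1": [60, 25, 10, 5], "MP1": [70, 20, 5, 5],
        }, index=["g1", "g2", "g3", "g4"])
        meta = _meta(1)
        meta.index = ["FC1", "FP1", "MC1", "MP1"]
        cm = CountMatrix(counts, meta)
        # CPM threshold 150000 -> keep genes with raw count > 15 in >= 3 samples
        out = filter_low_expression(cm, cpm_threshold=150_000, min_samples=3)
        assert list(out.counts.index) == ["g1", "g2"]


class TestDispersions:
    def test_poisson_truth_gives_near_zero_common(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 2000, size=2000)
        y = rng.poisson(mu[:, None], size=(2000, 12)).astype(float)
        X, _ = build_design(_meta(3))
        disp = estimate_dispersions(y, X, np.zeros(12) + np.log(1.0))
        assert disp.common < 0.01

    def test_nb_truth_recovered(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(100, 5000, size=2000)
        lam = rng.gamma(1 / 0.2, mu[:, None] * 0.2, size=(2000, 12))
        y = rng.poisson(lam).astype(float)
        X, _ = build_design(_meta(3))
        disp = estimate_dispersions(y, X, np.zeros(12))
        assert 0.15 < disp.common < 0.25

    def test_infinite_prior_df_collapses_to_common(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(10.0, 50.0, size=(300, 12))
        y = rng.poisson(lam).astype(float)
        X, _ = build_design(_meta(3))
        disp = estimate_dispersions(y, X, np.zeros(12), prior_df=np.inf)
        assert np.allclose(disp.tagwise, disp.common)

    def test_shrinkage_direction(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(100, 2000, size=500)
        lam = rng.gamma(1 / 0.1, mu[:, None] * 0.1, size=(500, 12))
        y = rng.poisson(lam).astype(float)
        X, _ = build_design(_meta(3))
        disp = estimate_dispersions(y, X, np.zeros(12))
        lo = np.minimum(disp.raw, disp.common) - 1e-12
        hi = np.maximum(disp.raw, disp.common) + 1e-12
        assert ((disp.tagwise >= lo) & (disp.tagwise <= hi)).all()


class TestNBGLM:
    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_saturated_group_design_recovers_group_means(self, phi):
        """With a two-group saturated design and equal offsets the NB MLE of
        each group mean is the arithmetic mean: (10,20) vs (40,80) gives a
        log2 fold change of exactly 2 for any dispersion."""
        y = np.array([[10.0, 20.0, 40.0, 80.0]])
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        fit = fit_nb_glm(y, X, np.zeros(4), phi)
        logfc = fit.beta[0, 1] * de_engine.LOG2E
        assert logfc == pytest.approx(2.0, abs=1e-6)

    def test_poisson_limit_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        y = rng.poisson(rng.uniform(5, 200, size=(20, 12)))
        X, _ = build_design(_meta(3))
        offset = np.log(rng.uniform(0.5, 2.0, size=12))
        fit = fit_nb_glm(y.astype(float), X, offset, 0.0)
        for g in range(20):
            ref = sm.GLM(y[g], X, family=sm.families.Poisson(),
                         offset=offset).fit()
            assert np.allclose(fit.beta[g], ref.params, atol=1e-6)

    def test_intercept_only_fitted_mean_is_offset_weighted_mean(self):
        # unequal offsets, Poisson: MLE of exp(b0) is sum(y)/sum(N)
        y = np.array([[3.0, 9.0, 30.0]])
        offset = np.log(np.array([1.0, 2.0, 10.0]))
        fit = fit_nb_glm(y, np.ones((3, 1)), offset, 0.0)
        assert np.exp(fit.beta[0, 0]) == pytest.approx(42.0 / 13.0, rel=1e-6)
        # equal offsets: the fitted mean is the arithmetic mean for any phi
        fit2 = fit_nb_glm(y, np.ones((3, 1)), np.zeros(3), 0.3)
        assert np.exp(fit2.beta[0, 0]) == pytest.approx(14.0, rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(UsageError):
            fit_nb_glm(np.ones((1, 4)), X, np.zeros(4), 0.1)


class TestLRT:
    def test_identical_designs_give_zero(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(100, size=(50, 12)).astype(float)
        X, _ = build_design(_meta(3))
        fit = fit_nb_glm(y, X, np.zeros(12), 0.1)
        lr, p = lrt_term(fit, fit)
        assert np.allclose(lr, 0) and np.allclose(p, 1)

    def test_reparameterization_invariance(self):
        """Treatment vs sum coding span the same model spaces; the LR of the
        interaction term is numerically identical."""
        rng = np.random.default_rng(9)
        lam = rng.gamma(5.0, 40.0, size=(200, 12))
        y = rng.poisson(lam).astype(float)
        meta = _meta(3)
        lrs = {}
        for coding in ("sum", "treatment"):
            Xf, _ = build_design(meta, coding=coding)
            Xr, _ = build_design(meta, ("sex", "diet"), coding=coding)
            ff = fit_nb_glm(y, Xf, np.zeros(12), 0.1)
            fr = fit_nb_glm(y, Xr, np.zeros(12), 0.1)
            lrs[coding] = lrt_term(ff, fr)[0]
        assert np.allclose(lrs["sum"], lrs["treatment"], atol=1e-4)

    def test_non_nested_rejected(self):
        meta = _meta(3)
        Xf, _ = build_design(meta, ("sex", "diet"))
        Xr, _ = build_design(meta, ("sex", "sex:diet"))
        ff = fit_nb_glm(np.ones((1, 12)), Xf, np.zeros(12), 0.1)
        fr = fit_nb_glm(np.ones((1, 12)), Xr, np.zeros(12), 0.1)
        with pytest.raises(UsageError):
            lrt_term(ff, fr)

    def test_power_at_planted_effect(self):
        """log2FC = 2 at 3 reps/cell, phi = 0.05: diet-term p-values are
        overwhelmingly small."""
        rng = np.random.default_rng(10)
        mu = np.full((300, 1), 200.0) * np.ones((1, 12))
        mu[:, [3, 4, 5, 9, 10, 11]] *= 4.0  # protein columns of _meta(3)
        lam = rng.gamma(1 / 0.05, mu * 0.05)
        y = rng.poisson(lam).astype(float)
        meta = _meta(3)
        Xf, _ = build_design(meta)
        Xr, _ = build_design(meta, ("sex", "sex:diet"))
        ff = fit_nb_glm(y, Xf, np.zeros(12), 0.05)
        fr = fit_nb_glm(y, Xr, np.zeros(12), 0.05)
        _, p = lrt_term(ff, fr)
        assert np.median(p) < 1e-3


class TestBH:
    def test_step_up_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_against_oracles(self):
        """1000 random vectors against both a sort-and-cummin oracle and
        statsmodels' implementation."""
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)

        def oracle(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            q = bh_adjust(p)
            assert np.allclose(q, oracle(p), atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(derandomize=True, max_examples=200)
    def test_properties(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in rank
        # ties share a q-value
        for val in np.unique(p):
            assert np.allclose(q[p == val], q[p == val][0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


class TestPerSexFoldChanges:
    def test_symmetric_counts_give_identical_fold_changes(self, small_sim):
        cm, _ = small_sim
        meta = cm.samples
        females = meta.index[meta["sex"] == "F"]
        counts = cm.counts.copy()
        # copy female counts onto the male samples, diet cell by diet cell
        for diet in ("C", "P"):
            f_cols = meta.index[(meta["sex"] == "F") & (meta["diet"] == diet)]
            m_cols = meta.index[(meta["sex"] == "M") & (meta["diet"] == diet)]
            counts[list(m_cols)] = counts[list(f_cols)].to_numpy()
        keep = counts.sum(axis=1) > 0
        cm2 = CountMatrix(counts.loc[keep], meta.copy())
        fc = per_sex_fold_changes(cm2)
        assert np.allclose(fc["logFC_female"], fc["logFC_male"])
        assert np.allclose(fc["q_female"], fc["q_male"])

    def test_orientation_higher_on_protein_is_positive(self):
        rng = np.random.default_rng(12)
        base = rng.integers(100, 2000, size=50).astype(float)
        mu = np.tile(base[:, None], (1, 12))
        mu[0, [3, 4, 5, 9, 10, 11]] *= 8  # gene 0 up on protein, both sexes
        y = rng.poisson(mu)
        cm = CountMatrix(pd.DataFrame(y, index=[f"g{i}" for i in range(50)],
                                      columns=_meta(3).index), _meta(3))
        fc = per_sex_fold_changes(cm)
        assert fc.loc[0, "logFC_female"] > 0
        assert fc.loc[0, "logFC_male"] > 0
        assert fc.loc[0, "flag"] == "both"

    def test_single_diet_level_rejected(self, small_sim):
        cm, _ = small_sim
        keep = cm.samples.index[(cm.samples["sex"] == "F")
                                | (cm.samples["diet"] == "C")]
        with pytest.raises(UsageError):
            per_sex_fold_changes(cm.subset_samples(keep))


class TestEdgeRCrossValidation:
    def test_tmm_and_common_dispersion_match_edger(self, small_sim, tmp_path):
        """Independent cross-check against the Bioconductor reference:
        TMM factors and the common NB dispersion agree with edgeR on the
        same simulated dataset."""
        import subprocess

        from sexdiet import tables_io

        cm, _ = small_sim
        tables_io.write_counts(cm, tmp_path / "c.tsv", tmp_path / "m.tsv")
        script = tmp_path / "ref.R"
        script.write_text("""
suppressMessages(library(edgeR))
counts <- read.delim("c.tsv", row.names=1)
meta <- read.delim("m.tsv", row.names=1)
design <- model.matrix(~factor(meta$sex)*factor(meta$diet))
y <- DGEList(counts=counts)
y <- calcNormFactors(y)
y <- estimateGLMCommonDisp(y, design)
cat(sprintf("%.10f ", y$samples$norm.factors), "\\n")
cat(sprintf("%.8f", y$common.dispersion), "\\n")
""")
        res = subprocess.run(["Rscript", "ref.R"], cwd=tmp_path,
                             capture_output=True, text=True, timeout=600)
        assert res.returncode == 0, res.stderr
        lines = [ln for ln in res.stdout.strip().splitlines() if ln.strip()]
        ref_factors = np.array([float(x) for x in lines[0].split()])
        ref_common = float(lines[1])

        nf = tmm_normalize(cm)
        assert np.allclose(nf.factors, ref_factors, atol=1e-4)
        y = cm.counts.to_numpy(float)
        X, _ = build_design(cm.samples, coding="treatment")
        disp = estimate_dispersions(y, X, nf.offsets())
        assert disp.common == pytest.approx(ref_common, rel=0.05)
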