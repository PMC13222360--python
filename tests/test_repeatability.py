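"""Variance-component estimation, inference machinery and the sensitivity
and distance-class analyses.

The REML estimator is checked against two independent oracles: the
balanced one-way ANOVA intraclass correlation (closed form) and
statsmodels' MixedLM (independent numerical implementation).
"""

import numpy as np
import pandas as pd
import pytest

from flyway.config import PipelineConfig
from flyway.exceptions import AliasingError, DegenerateVarianceError, InestimableError
from flyway.repeatability import (
    _GroupedDesign,
    adjusted_repeatability,
    bootstrap_ci,
    build_design,
    count_pathway,
    distance_class_trend,
    fit_poisson_glmm,
    fit_random_intercept_lmm,
    overdispersion_ratio,
    permutation_pvalue,
    sensitivity_suite,
)
from flyway.simulate import simulate_repeatability_table


def anova_icc(y, ids, k):
    """Balanced one-way ANOVA ICC: (MSB - MSW) / (MSB + (k-1) MSW)."""
    groups = [y[ids == g] for g in np.unique(ids)]
    msb = k * np.var([g.mean() for g in groups], ddof=1)
    msw = np.mean([np.var(g, ddof=1) for g in groups])
    return (msb - msw) / (msb + (k - 1) * msw)


class TestGaussianFit:
    def test_matches_anova_icc_worked_example(self):
        y = np.array([1, 2, 5, 6, 9, 10], dtype=float)
        ids = np.array(["A", "A", "B", "B", "C", "C"])
        comp = fit_random_intercept_lmm(y, np.ones((6, 1)), ids)
        oracle = anova_icc(y, ids, k=2)
        assert oracle == pytest.approx(0.969, abs=5e-4)
        assert comp.repeatability == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_anova_icc_on_balanced_noise(self, seed):
        rng = np.random.default_rng(seed)
        ids = np.repeat(np.arange(25), 4)
        y = rng.normal(0, 1, 100) + rng.normal(0, 1.5, 25)[ids]
        oracle = anova_icc(y, ids, k=4)
        comp = fit_random_intercept_lmm(y, np.ones((100, 1)), ids)
        if oracle > 0:
            assert comp.repeatability == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        tab = simulate_repeatability_table(0.5, 40, 3, seed=3)
        y, X, names, ids, _ = build_design(tab, "y")
        comp = fit_random_intercept_lmm(y, X, ids, names)
        m = sm.MixedLM(y, X, groups=ids).fit(reml=True)
        assert comp.sigma2_id == pytest.approx(float(np.asarray(m.cov_re)[0, 0]), abs=1e-4)
        assert comp.sigma2_res == pytest.approx(m.scale, abs=1e-4)
        assert np.allclose(comp.beta, m.fe_params, atol=1e-5)

    def test_zero_within_variance_boundary(self):
        y = np.array([1.0, 1.0, 5.0, 5.0, 9.0, 9.0])
        ids = np.array(["A", "A", "B", "B", "C", "C"])
        comp = fit_random_intercept_lmm(y, np.ones((6, 1)), ids)
        assert comp.repeatability > 0.999999

    def test_null_data_hits_lambda_zero_boundary(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(40):
            ids = np.repeat(np.arange(30), 3)
            y = rng.normal(0, 1, 90)
            comp = fit_random_intercept_lmm(y, np.ones((90, 1)), ids)
            hits += comp.sigma2_id == 0.0
        assert 10 <= hits <= 35  # boundary mass is roughly one half

    def test_affine_invariance(self):
        tab = simulate_repeatability_table(0.6, 30, 3, seed=4)
        r1 = adjusted_repeatability(tab, "y", config=_fast()).R
        tab2 = tab.assign(y=2.0 * tab["y"] + 7.0)
        r2 = adjusted_repeatability(tab2, "y", config=_fast()).R
        assert r1 == pytest.approx(r2, abs=1e-6)  # limited by the 1-D search tolerance

    def test_inestimable_without_repeats(self):
        y = np.arange(4.0)
        ids = np.array(["a", "b", "c", "d"])
        with pytest.raises(InestimableError):
            fit_random_intercept_lmm(y, np.ones((4, 1)), ids)

    def test_constant_response_degenerate(self):
        ids = np.repeat(["a", "b"], 3)
        with pytest.raises(DegenerateVarianceError):
            fit_random_intercept_lmm(np.ones(6), np.ones((6, 1)), ids)

    def test_aliased_design_raises_when_asked(self):
        tab = simulate_repeatability_table(0.5, 12, 3, seed=5)
        tab["dup"] = tab["cluster"]  # perfectly aliased with cluster
        with pytest.raises(AliasingError, match="dup"):
            build_design(tab, "y", extra_covariates=("dup",), drop_aliased=False)


def _fast(n_boot=0, n_perm=0, seed=0):
    return PipelineConfig(n_boot=n_boot, n_perm=n_perm, seed=seed)


class TestInference:
    def test_bootstrap_deterministic_under_seed(self):
        tab = simulate_repeatability_table(0.5, 30, 3, seed=6)
        r1 = adjusted_repeatability(tab, "y", config=_fast(n_boot=100, seed=9))
        r2 = adjusted_repeatability(tab, "y", config=_fast(n_boot=100, seed=9))
        assert r1.ci95 == r2.ci95

    def test_bootstrap_boundary_lower_bound_zero(self):
        tab = simulate_repeatability_table(0.0, 40, 3, seed=7)
        res = adjusted_repeatability(tab, "y", config=_fast(n_boot=200, seed=1))
        assert res.ci95[0] == pytest.approx(0.0, abs=1e-9)

    def test_estimate_within_ci_for_strong_signal(self):
        tab = simulate_repeatability_table(0.8, 50, 4, seed=8)
        res = adjusted_repeatability(tab, "y", config=_fast(n_boot=300, seed=2))
        assert res.ci95[0] <= 0.8 <= res.ci95[1]

    def test_permutation_p_small_for_strong_signal(self):
        tab = simulate_repeatability_table(0.7, 50, 4, seed=9)
        res = adjusted_repeatability(tab, "y", config=_fast(n_perm=200, seed=3))
        assert res.p_perm <= 0.01

    def test_permutation_p_never_zero(self):
        tab = simulate_repeatability_table(0.9, 40, 4, seed=10)
        y, X, names, ids, _ = build_design(tab, "y")
        p = permutation_pvalue(y, X, ids, 0.9, n_perm=50, seed=4)
        assert p >= 1.0 / 51.0

    def test_null_p_roughly_uniform(self):
        ps = []
        for rep in range(40):
            tab = simulate_repeatability_table(0.0, 25, 3, seed=100 + rep)
            y, X, names, ids, _ = build_design(tab, "y")
            comp = fit_random_intercept_lmm(y, X, ids)
            ps.append(permutation_pvalue(y, X, ids, comp.repeatability, 60, seed=rep))
        assert 0.2 < np.mean(ps) < 0.8


class TestCountPathway:
    def test_poisson_data_takes_poisson_path(self):
        # weak latent signal: conditional dispersion stays near 1
        tab = simulate_repeatability_table(0.05, 60, 4, family="count", seed=11)
        y, X, names, ids, _ = build_design(tab, "y")
        fam, comp, ratio = count_pathway(y.astype(int), X, ids, names)
        # oracle: direct Pearson statistic
        assert ratio == pytest.approx(overdispersion_ratio(y, X), rel=1e-9)
        assert fam == "poisson_latent"
        assert 0.0 <= comp.repeatability <= 1.0

    def test_overdispersed_counts_fall_back_to_sqrt_gaussian(self):
        rng = np.random.default_rng(12)
        ids = np.repeat(np.arange(40), 4)
        lam = rng.gamma(1.0, 5.0, 160)  # NB-style dispersion >> 1.5
        y = rng.poisson(lam)
        X = np.ones((160, 1))
        fam, comp, ratio = count_pathway(y, X, ids)
        assert ratio > 1.5
        assert fam == "sqrt_gaussian"

    def test_poisson_glmm_recovers_latent_variance(self):
        rng = np.random.default_rng(13)
        sigma2 = 0.4
        ids = np.repeat(np.arange(150), 4)
        u = rng.normal(0, np.sqrt(sigma2), 150)
        y = rng.poisson(np.exp(np.log(4.0) + u[ids]))
        comp, lam_bar = fit_poisson_glmm(y, np.ones((600, 1)), ids)
        assert comp.sigma2_id == pytest.approx(sigma2, abs=0.1)

    def test_all_zero_counts_degenerate(self):
        ids = np.repeat(np.arange(5), 2)
        with pytest.raises(DegenerateVarianceError):
            count_pathway(np.zeros(10, dtype=int), np.ones((10, 1)), ids)

    def test_non_integer_rejected(self):
        ids = np.repeat(np.arange(5), 2)
        with pytest.raises(TypeError):
            count_pathway(np.full(10, 1.5), np.ones((10, 1)), ids)


class TestSensitivity:
    def _records(self, seed=14):
        tab = simulate_repeatability_table(0.6, 30, 4, seed=seed)
        return tab.rename(columns={"cluster": "cluster_id"})

    def test_identical_pooling_gives_identical_r(self):
        rec = self._records()
        per_trait, pairwise, cov = sensitivity_suite(
            {150.0: rec, 250.0: rec.copy()}, traits=("y",), config=_fast()
        )
        row = pairwise.iloc[0]
        assert row["pearson_r"] == 1.0 or np.isnan(row["pearson_r"])
        assert row["mean_abs_dR"] == pytest.approx(0.0, abs=1e-12) or row["excluded"]

    def test_collapsed_clusters_flagged_unstable(self):
        rec = self._records()
        collapsed = rec.assign(cluster_id="all")
        per_trait, pairwise, cov = sensitivity_suite(
            {250.0: rec, 500.0: collapsed}, traits=("y",), config=_fast()
        )
        flags = per_trait.set_index("radius_km")["unstable"]
        assert flags.loc[500.0].all()
        assert bool(pairwise.iloc[0]["excluded"])

    def test_covariate_sensitivity_columns(self):
        rec = self._records()
        rec["sex"] = np.where(pd.factorize(rec["id"])[0] % 2 == 0, "F", "M")
        rec["capture_country"] = "DE"
        cfg = _fast()
        per_trait, pairwise, cov = sensitivity_suite({250.0: rec}, traits=("y",), config=cfg)
        assert {"R_base", "R_extra", "dR"} <= set(cov.columns)
        assert np.isfinite(cov["dR"]).all()


class TestDistanceClassTrend:
    def _table(self, rs):
        rows = []
        for trait, vals in rs.items():
            for cls, r in zip(("short", "medium", "long"), vals):
                rows.append({"trait": trait, "season": "spring", "distance_class": cls, "R": r})
        return pd.DataFrame(rows)

    def test_flat_r_gives_zero_slope(self):
        # constant within trait: every trait dropped, slope undefined
        t = self._table({"a": (0.5, 0.5, 0.5), "b": (0.7, 0.7, 0.7)})
        out = distance_class_trend(t)
        assert out.iloc[0]["n_traits"] == 0

    def test_linear_increase_gives_half_slope(self):
        # R rising 0.2/class rescales to (0, 0.5, 1): OLS slope 0.5 exactly
        t = self._table({"a": (0.2, 0.4, 0.6), "b": (0.1, 0.3, 0.5)})
        out = distance_class_trend(t)
        assert out.iloc[0]["slope"] == pytest.approx(0.5, abs=1e-9)

    def test_mixed_trends_ci_spans_zero(self):
        t = self._table({"a": (0.2, 0.6, 0.4), "b": (0.6, 0.2, 0.4), "c": (0.4, 0.4001, 0.39)})
        out = distance_class_trend(t)
        assert out.iloc[0]["ci_lo"] < 0 < out.iloc[0]["ci_hi"]
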