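"""Tests for the comparative-statistics pipeline."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from finswim import compstats as cs
from finswim import morphometrics as mm
from finswim import reproduce, synthdata, trees
from finswim.synthdata import SyntheticConfig


def _design_from(mpf_dataset):
    records, tree, truth = mpf_dataset
    return cs.build_design(records, "MPF"), records, tree, truth


class TestBuildDesign:
    def test_columns_standardised(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        for name, col in design.columns.items():
            assert abs(col.mean()) < 1e-10, name
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-10), name
        assert abs(design.response.mean()) < 1e-10

    def test_quadratic_built_from_centred_unscaled_f(self, mpf_dataset):
        design, records, _, truth = _design_from(mpf_dataset)
        f = truth["f"]
        fsq = (f - f.mean()) ** 2
        expected = (fsq - fsq.mean()) / fsq.std(ddof=1)
        assert np.allclose(design.columns["f2"], expected)

    def test_metadata_matches_hand_computation(self, mpf_dataset):
        design, records, _, truth = _design_from(mpf_dataset)
        assert design.meta["f_mean"] == pytest.approx(truth["f"].mean())
        assert design.meta["f_sd"] == pytest.approx(truth["f"].std(ddof=1))
        assert design.meta["logM_mean"] == pytest.approx(truth["logM"].mean())

    def test_zero_variance_predictor_errors(self):
        records = [
            mm.SpeciesRecord(f"s{i}", "MPF", 0.1, 0.04, 0.01, 0.02, 2.5, 0.3 + 0.01 * i)
            for i in range(8)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            cs.build_design(records, "MPF")

    def test_too_few_records_errors(self, mpf_dataset):
        records, *_ = mpf_dataset
        with pytest.raises(ValueError, match="at least 6"):
            cs.build_design(records[:4], "MPF")


class TestFitPgls:
    def test_matches_statsmodels_ols(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        fit = cs.fit_pgls(design, None, cs.PREDICTORS)
        res = sm.OLS(design.response, design.matrix(cs.PREDICTORS)).fit()
        assert np.allclose(fit.beta.values, res.params)
        assert np.allclose(fit.se.values, res.bse)
        assert np.allclose(fit.pvalues.values, res.pvalues)
        assert fit.loglik == pytest.approx(res.llf)
        assert fit.r2 == pytest.approx(res.rsquared)
        assert fit.adj_r2 == pytest.approx(res.rsquared_adj)

    def test_matches_statsmodels_gls_at_fixed_sigma(self, mpf_dataset):
        design, records, tree, _ = _design_from(mpf_dataset)
        _, V = trees.vcv_matrix(tree, labels=design.species)
        sigma = cs._lambda_cov(V, 0.5)
        X = design.matrix(("f", "AR"))
        beta, cov_unscaled, rss, _, _, _ = cs._gls_core(design.response, X, sigma)
        res = sm.GLS(design.response, X, sigma=sigma).fit()
        assert np.allclose(beta, res.params)
        se = np.sqrt(np.diag(cov_unscaled) * rss / (X.shape[0] - X.shape[1]))
        assert np.allclose(se, res.bse)

    def test_star_phylogeny_equals_ols(self, star_tree, rng):
        labels = trees.leaf_labels(star_tree)
        n = len(labels)
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        design = cs.DesignMatrix(
            gait="MPF", species=labels,
            response=(y - y.mean()) / y.std(ddof=1),
            columns={"f": (x - x.mean()) / x.std(ddof=1)},
            meta={},
        )
        gls = cs.fit_pgls(design, star_tree, ("f",))
        ols = cs.fit_pgls(design, None, ("f",))
        assert np.allclose(gls.beta.values, ols.beta.values, atol=1e-8)

    def test_lambda_recovery_on_brownian_residuals(self, rng):
        errs = []
        for _ in range(30):
            tree = synthdata.simulate_tree(200, 1.0, rng=rng)
            cfg = SyntheticConfig(n=200, lambda_true=0.8)
            recs, _ = synthdata.simulate_records(cfg, tree=tree, rng=rng)
            fit = cs.fit_pgls(cs.build_design(recs, "MPF"), tree)
            errs.append(fit.lambda_ - 0.8)
        assert abs(np.median(errs)) <= 0.15

    def test_unknown_predictor_errors(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        with pytest.raises(ValueError, match="unknown predictors"):
            cs.fit_pgls(design, None, ("f", "girth"))


class TestAicc:
    def test_reduces_to_aic_for_large_n(self):
        small = cs.aicc(-100.0, 4, 20)
        huge = cs.aicc(-100.0, 4, 10**7)
        assert huge == pytest.approx(-2 * -100.0 + 2 * 4, abs=1e-4)
        assert small > huge

    def test_fewer_parameters_win_at_equal_likelihood(self):
        assert cs.aicc(-10.0, 2, 20) < cs.aicc(-10.0, 3, 20)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError, match="n > k"):
            cs.aicc(-10.0, 5, 6)

    def test_accepts_model_fit(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        fit = cs.fit_pgls(design, None, ("AR",))
        assert cs.aicc(fit) == pytest.approx(fit.aicc)


class TestEnumerateAndAverage:
    def test_sixteen_candidates(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        ms = cs.enumerate_and_retain(design)
        assert len(ms.fits) == 16
        assert {f.predictors for f in ms.fits} >= {(), ("f2",), ("f", "f2", "AR", "logM")}
        assert ms.delta.min() == 0.0
        assert np.nansum(ms.weights) == pytest.approx(1.0)

    def test_orthogonal_response_prefers_intercept_only(self, mpf_dataset):
        # response residualised against every predictor: all candidate
        # models share the likelihood, so the smallest k must win
        design, *_ = _design_from(mpf_dataset)
        X = design.matrix(cs.PREDICTORS)
        noise = np.random.default_rng(0).normal(size=design.n)
        resid = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        design.response = (resid - resid.mean()) / resid.std(ddof=1)
        ms = cs.enumerate_and_retain(design)
        assert ms.best.predictors == ()

    def test_retention_monotone_in_delta_max(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        narrow = cs.enumerate_and_retain(design, delta_max=1.0, soft_margin=0.0)
        wide = cs.enumerate_and_retain(design, delta_max=4.0, soft_margin=0.0)
        assert np.all(wide.retained[narrow.retained])
        assert wide.retained.sum() >= narrow.retained.sum()

    def test_soft_margin_admits_near_misses(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        hard = cs.enumerate_and_retain(design, delta_max=2.0, soft_margin=0.0)
        soft = cs.enumerate_and_retain(design, delta_max=2.0, soft_margin=0.2)
        assert np.all(soft.retained[hard.retained])
        assert np.all(soft.delta[soft.retained] <= 2.2 + 1e-12)

    def test_two_model_weights(self):
        fits = [_dummy_fit(("AR",), aicc=100.0), _dummy_fit(("f",), aicc=102.0)]
        ms = cs.ModelSet(
            fits=fits, delta=np.array([0.0, 2.0]),
            retained=np.array([True, True]),
            weights=np.exp([-0.0, -1.0]) / np.exp([-0.0, -1.0]).sum(),
            delta_max=2.0, soft_margin=0.2,
        )
        assert ms.weights[0] == pytest.approx(0.7310585786, rel=1e-9)
        assert ms.weights[1] == pytest.approx(0.2689414214, rel=1e-9)

    def test_single_model_average_is_identity(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        fit = cs.fit_pgls(design, None, ("AR", "logM"))
        ms = cs.ModelSet(
            fits=[fit], delta=np.array([0.0]), retained=np.array([True]),
            weights=np.array([1.0]), delta_max=2.0, soft_margin=0.2,
        )
        avg = cs.model_average(ms)
        assert avg.coef["AR"] == pytest.approx(fit.beta["AR"])
        assert avg.coef["logM"] == pytest.approx(fit.beta["logM"])
        assert "f" not in avg.coef  # absent, not zero

    def test_conditional_average_hand_example(self):
        fit1 = _dummy_fit(("f", "AR"), aicc=100.0, beta={"f": 0.2, "AR": 0.8})
        fit2 = _dummy_fit(("AR",), aicc=101.0, beta={"AR": 0.6})
        ms = cs.ModelSet(
            fits=[fit1, fit2], delta=np.array([0.0, 1.0]),
            retained=np.array([True, True]),
            weights=np.array([0.6224593312, 0.3775406688]),
            delta_max=2.0, soft_margin=0.2,
        )
        avg = cs.model_average(ms)
        assert avg.coef["f"] == pytest.approx(0.2)  # only model containing f
        assert avg.coef["AR"] == pytest.approx(0.6224593312 * 0.8 + 0.3775406688 * 0.6)

    def test_model_table_layout(self, mpf_dataset):
        design, *_ = _design_from(mpf_dataset)
        table = cs.enumerate_and_retain(design).to_frame()
        assert list(table["AICc"]) == sorted(table["AICc"])
        for col in ("beta_AR", "P_AR", "adjR2", "dAICc", "retained"):
            assert col in table.columns


def _dummy_fit(predictors, aicc, beta=None, se=None):
    beta = beta or {p: 0.5 for p in predictors}
    names = ["intercept", *predictors]
    return cs.ModelFit(
        predictors=tuple(predictors),
        beta=pd.Series([0.0] + [beta[p] for p in predictors], index=names),
        se=pd.Series([0.1] * len(names), index=names),
        pvalues=pd.Series([0.5] * len(names), index=names),
        lambda_=None, loglik=0.0, k=len(names) + 1, n=50, aicc=aicc,
        r2=0.5, adj_r2=0.45, sigma2=0.2,
    )


class TestBootstrap:
    def test_single_replicate_interval_collapses(self, mpf_dataset):
        records, tree, _ = mpf_dataset
        avg = cs.bootstrap_cis(records, "MPF", None, n_boot=1, seed=11)
        for pred, iv in avg.intervals.items():
            lo, hi = iv[95]
            assert lo == pytest.approx(hi)
            assert iv[50][0] == pytest.approx(lo)

    def test_bit_reproducible_given_seed(self, mpf_dataset):
        records, *_ = mpf_dataset
        a = cs.bootstrap_cis(records, "MPF", None, n_boot=20, seed=3)
        b = cs.bootstrap_cis(records, "MPF", None, n_boot=20, seed=3)
        assert a.intervals == b.intervals
        assert a.coef == b.coef

    def test_interval_nesting(self, mpf_dataset):
        records, *_ = mpf_dataset
        avg = cs.bootstrap_cis(records, "MPF", None, n_boot=150, seed=5)
        for pred, iv in avg.intervals.items():
            assert iv[95][0] <= iv[75][0] <= iv[50][0] <= iv[50][1] <= iv[75][1] <= iv[95][1]
        # point estimate lies inside its own 95% interval on clean data
        for pred, value in avg.coef.items():
            lo, hi = avg.intervals[pred][95]
            assert lo <= value <= hi

    def test_null_coefficient_interval_covers_zero(self, rng):
        covered = 0
        n_outer = 25
        for _ in range(n_outer):
            cfg = SyntheticConfig(n=60, beta=(0.0, 0.0, 0.7, 0.2))
            recs, _ = synthdata.simulate_records(cfg, rng=rng)
            avg = cs.bootstrap_cis(recs, "MPF", None, n_boot=99,
                                   seed=int(rng.integers(2**31)))
            if "f" not in avg.intervals:
                continue
            lo, hi = avg.intervals["f"][95]
            covered += lo <= 0.0 <= hi
        assert covered >= 0.8 * n_outer


class TestAdjustedUmax:
    def test_residual_properties(self, mpf_dataset):
        records, *_ = mpf_dataset
        adj = cs.adjusted_umax(records, "MPF")
        u = np.array([r.umax for r in records])
        m3 = np.array([r.mass for r in records]) ** (1 / 3)
        ar = np.array([r.fin_aspect_ratio for r in records])
        assert adj.mean() == pytest.approx(u.mean())
        resid = adj.to_numpy() - u.mean()
        assert np.corrcoef(resid, m3)[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert np.corrcoef(resid, ar)[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_covariates_leave_umax_unchanged(self):
        # U_max exactly orthogonal to centred M^(1/3) and AR => residuals
        # reproduce the original speeds
        rng = np.random.default_rng(1)
        n = 24
        m3 = rng.uniform(0.1, 0.5, n)
        ar = rng.uniform(1.5, 3.5, n)
        X = np.column_stack([np.ones(n), m3, ar])
        u = rng.uniform(0.2, 0.8, n)
        u_perp = u - X @ np.linalg.lstsq(X, u, rcond=None)[0] + u.mean()
        records = [
            mm.SpeciesRecord(f"s{i}", "MPF", 0.1, 0.04, 0.02, float(m3[i]) ** 3,
                             float(ar[i]), float(u_perp[i]))
            for i in range(n)
        ]
        adj = cs.adjusted_umax(records, "MPF")
        assert np.allclose(adj.to_numpy(), u_perp)

    def test_rank_deficient_design_errors(self):
        records = [
            mm.SpeciesRecord(f"s{i}", "MPF", 0.1, 0.04, 0.02, 0.02, 2.5, 0.3 + 0.01 * i)
            for i in range(8)
        ]
        with pytest.raises(ValueError, match="rank deficient"):
            cs.adjusted_umax(records, "MPF")


class TestMechanisticR2AndPermutation:
    def test_perfect_model(self, rng):
        a = rng.normal(size=30)
        assert cs.mechanistic_r2(a, a.copy()) == pytest.approx(1.0)

    def test_constant_model_explains_nothing(self, rng):
        a = rng.normal(size=30)
        assert cs.mechanistic_r2(a, np.full(30, 7.0)) == pytest.approx(0.0)

    def test_recentring_removes_elevation(self, rng):
        a = rng.normal(size=30)
        m = rng.normal(size=30)
        assert cs.mechanistic_r2(a, m) == pytest.approx(cs.mechanistic_r2(a, m + 100.0))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            cs.mechanistic_r2(np.ones(5), np.arange(5.0))

    def test_perfect_prediction_gives_minimum_p(self, rng):
        a = rng.normal(size=20)
        res = cs.permutation_test(a, a.copy(), n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_permutation_reproducible(self, rng):
        a = rng.normal(size=25)
        m = rng.normal(size=25)
        r1 = cs.permutation_test(a, m, n_perm=99, seed=42)
        r2 = cs.permutation_test(a, m, n_perm=99, seed=42)
        assert r1 == r2


class TestPicCorrelations:
    def test_star_tree_equals_raw(self, rng):
        n = 14
        newick = "(" + ",".join(f"sp{i + 1}:1.0" for i in range(n)) + ");"
        star = dendropy.Tree.get(data=newick, schema="newick")
        cfg = SyntheticConfig(n=n)
        recs, _ = synthdata.simulate_records(cfg, rng=rng)
        out = cs.pic_correlations(recs, star)
        assert np.allclose(out.pic.values, out.raw.values, atol=1e-10)

    def test_two_species_correlation_undefined(self):
        tree = dendropy.Tree.get(data="(sp1:1,sp2:1);", schema="newick")
        recs = [
            mm.SpeciesRecord("sp1", "MPF", 0.1, 0.04, 0.02, 0.02, 2.0, 0.3),
            mm.SpeciesRecord("sp2", "MPF", 0.12, 0.05, 0.02, 0.03, 2.5, 0.4),
        ]
        out = cs.pic_correlations(recs, tree)
        assert np.isnan(out.pic.loc["f", "AR"])
        assert out.n_contrasts == 1

    def test_combined_table_layout(self, mpf_dataset, rng):
        records, tree, _ = mpf_dataset
        out = cs.pic_correlations(records, tree)
        combined = out.combined()
        # below diagonal raw, above diagonal PIC
        assert combined.iloc[2, 0] == pytest.approx(out.raw.iloc[2, 0])
        assert combined.iloc[0, 2] == pytest.approx(out.pic.iloc[0, 2])
        assert np.isnan(combined.iloc[1, 1])


class TestQuadraticVertex:
    def test_pure_quadratic_vertex_at_mean(self):
        avg = cs.AveragedCoefficients(coef={"f": 0.0, "f2": -0.3}, se={})
        meta = {"f_mean": 3.5, "f_sd": 1.0, "f2_sd": 1.5, "f_min": 1.0, "f_max": 6.0}
        v = cs.quadratic_vertex(avg, meta)
        assert v.f_vertex == pytest.approx(3.5)
        assert v.is_maximum

    def test_upward_parabola_flagged(self):
        avg = cs.AveragedCoefficients(coef={"f": 0.1, "f2": 0.2}, se={})
        meta = {"f_mean": 3.5, "f_sd": 1.0, "f2_sd": 1.5, "f_min": 1.0, "f_max": 6.0}
        assert not cs.quadratic_vertex(avg, meta).is_maximum

    def test_missing_coefficients_error(self):
        avg = cs.AveragedCoefficients(coef={"f2": -0.3}, se={})
        with pytest.raises(ValueError, match="linear and quadratic"):
            cs.quadratic_vertex(avg, {"f_mean": 3.0, "f_sd": 1.0, "f2_sd": 1.0,
                                      "f_min": 1, "f_max": 6})

    def test_known_vertex_recovered_from_synthetic_data(self, rng):
        # generating coefficients chosen so the response peaks at f = 4.0
        target = 4.0
        estimates = []
        for _ in range(10):
            cfg = SyntheticConfig(n=100, gait="BCF", f_mean=3.5, f_sd=1.1,
                                  beta=(0.0, -0.35, 0.5, 0.2), residual_sd=0.3)
            recs, truth = synthdata.simulate_records(cfg, rng=rng)
            design = cs.build_design(recs, "BCF")
            # shift the response so its maximum sits at `target` instead of
            # the mean fineness: add the linear term implied by the vertex
            b2 = -0.35
            b1 = -2 * b2 * (design.meta["f_sd"] / design.meta["f2_sd"]) * (
                target - design.meta["f_mean"]
            )
            y = design.response + b1 * design.columns["f"] - 0.0
            design.response = (y - y.mean()) / y.std(ddof=1)
            fit = cs.fit_pgls(design, None, cs.PREDICTORS)
            avg = cs.AveragedCoefficients(
                coef={"f": fit.beta["f"], "f2": fit.beta["f2"]}, se={}
            )
            estimates.append(cs.quadratic_vertex(avg, design.meta).f_vertex)
        assert np.median(estimates) == pytest.approx(target, abs=0.3)

    def test_effect_range_reported(self):
        avg = cs.AveragedCoefficients(coef={"f": 0.2, "f2": -0.25}, se={})
        meta = {"f_mean": 3.0, "f_sd": 1.0, "f2_sd": 2.0, "f_min": 1.5, "f_max": 6.0}
        v = cs.quadratic_vertex(avg, meta)
        assert v.effect_at_fmin > v.effect_at_fmax  # negative curvature
        assert v.effect_at_fmin == pytest.approx(0.2 + 2 * -0.25 * 0.5 * (1.5 - 3.0))
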