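"""FIML variance components: density oracle, parameter recovery, nested-model
ordering, homogeneity and sex-limitation calibration, bivariate Cholesky."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinscales as ts
from twinscales.twin_models import (
    build_families,
    fiml_loglik,
    fit_bivariate,
    fit_univariate,
    omnibus_homogeneity_test,
    sex_limitation_check,
)


def _theta_scores(truth, cols=("trait_0",), names=("score",)):
    out = truth.theta[["person_id"]].copy()
    for c, n in zip(cols, names):
        out[n] = truth.theta[c]
    return out


def _simulate(a2=0.41, n_mz=226, n_dz=408, p_sib=84 / 634, n_single=28, seed=0, **kw):
    cfg = ts.make_config(n_mz_pairs=n_mz, n_dz_pairs=n_dz, p_extra_sib=p_sib,
                         n_singletons=n_single,
                         trait_params=[(a2, 0.0, 1 - a2), (a2, 0.0, 1 - a2)],
                         seed=seed, **kw)
    _, ped, truth = ts.simulate_cohort(cfg)
    return ped, truth


class TestFimlLoglik:
    def test_complete_mz_trio_matches_mvn_density_oracle(self):
        ped = pd.DataFrame({
            "family_id": [1, 1, 1], "person_id": ["a", "b", "c"],
            "zygosity": "MZ", "role": ["twin1", "twin2", "sib"],
            "sex": "F", "age": 12.0})
        scores = pd.DataFrame({"person_id": ["a", "b", "c"], "score": [0.3, -0.2, 1.1]})
        fg = build_families(scores, ped)
        vA, vC, vE = 0.5, 0.2, 0.3
        beta = np.array([0.1])
        got = fiml_loglik(fg, np.array([[vA]]), np.array([[vC]]), np.array([[vE]]),
                          model="ACE", beta=beta)
        R = np.array([[1, 1, 0.5], [1, 1, 0.5], [0.5, 0.5, 1]])
        Sigma = vA * R + vC * np.ones((3, 3)) + vE * np.eye(3)
        expected = stats.multivariate_normal.logpdf([0.3, -0.2, 1.1],
                                                    [0.1, 0.1, 0.1], Sigma)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_singletons_reduce_to_univariate_normals(self):
        ped = pd.DataFrame({"family_id": [1, 2], "person_id": ["a", "b"],
                            "zygosity": "none", "role": "singleton",
                            "sex": "F", "age": 12.0})
        scores = pd.DataFrame({"person_id": ["a", "b"], "score": [0.5, -1.0]})
        fg = build_families(scores, ped)
        got = fiml_loglik(fg, np.array([[0.4]]), None, np.array([[0.6]]),
                          model="AE", beta=np.array([0.0]))
        expected = stats.norm.logpdf([0.5, -1.0], 0.0, 1.0).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_a_makes_mz_and_dz_blocks_identical(self):
        for zyg in ("MZ", "DZ"):
            ped = pd.DataFrame({"family_id": [1, 1], "person_id": ["a", "b"],
                                "zygosity": zyg, "role": ["twin1", "twin2"],
                                "sex": "F", "age": 12.0})
            scores = pd.DataFrame({"person_id": ["a", "b"], "score": [0.4, -0.4]})
            fg = build_families(scores, ped)
            ll = fiml_loglik(fg, np.array([[0.0]]), np.array([[0.3]]),
                             np.array([[0.7]]), model="ACE", beta=np.array([0.0]))
            if zyg == "MZ":
                ll_mz = ll
        assert ll == pytest.approx(ll_mz, abs=1e-12)

    def test_fiml_on_complete_pairs_matches_closed_form_gaussian_mle(self):
        # saturated check: with one zygosity group the AE MLE reproduces the
        # moment structure implied by the fitted covariance
        ped, truth = _simulate(a2=0.5, n_mz=400, n_dz=0, p_sib=0, n_single=0, seed=3)
        vc = fit_univariate(_theta_scores(truth), ped, model="AE", seed=0)
        pairs = truth.theta.merge(truth.family, on="person_id").pivot_table(
            index="family_id", columns="role", values="trait_0")[["twin1", "twin2"]].dropna()
        emp_cov = np.cov(pairs.to_numpy(), rowvar=False, ddof=0)
        vA, _, vE = vc.variances
        # implied MZ covariance must match the empirical one closely
        assert vA == pytest.approx(emp_cov[0, 1], abs=0.05)
        assert vA + vE == pytest.approx(np.diag(emp_cov).mean(), abs=0.05)


class TestUnivariateFit:
    def test_ae_recovery_at_study_composition(self):
        vals = []
        for rep in range(6):
            ped, truth = _simulate(a2=0.42, seed=100 + rep)
            vc = fit_univariate(_theta_scores(truth), ped, model="AE", seed=rep)
            vals.append(vc.a2)
        assert np.mean(vals) == pytest.approx(0.42, abs=0.06)

    def test_proportions_sum_to_one_and_aic_formula(self):
        ped, truth = _simulate(seed=5)
        vc = fit_univariate(_theta_scores(truth), ped, model="ACE", seed=0)
        assert vc.a2 + vc.c2_or_d2 + vc.e2 == pytest.approx(1.0, abs=1e-9)
        assert vc.aic == pytest.approx(vc.minus2ll + 2 * vc.n_params)

    def test_perfect_mz_correlation_drives_a2_to_one(self):
        ped, truth = _simulate(a2=1.0 - 1e-9, n_mz=300, n_dz=300, p_sib=0,
                               n_single=0, seed=6)
        vc = fit_univariate(_theta_scores(truth), ped, model="AE", seed=0)
        assert vc.a2 > 0.97

    def test_null_a_lrt_calibrated(self):
        # pure-noise data: dropping A should rarely be significant
        sig = 0
        for rep in range(30):
            ped, truth = _simulate(a2=0.0, n_mz=100, n_dz=150, p_sib=0,
                                   n_single=0, seed=200 + rep)
            scores = _theta_scores(truth)
            ae = fit_univariate(scores, ped, model="AE", seed=0)
            e = fit_univariate(scores, ped, model="E", seed=0)
            lrt = e.minus2ll - ae.minus2ll
            sig += stats.chi2.sf(max(lrt, 0.0), 1) < 0.05
        assert sig <= 3  # <= 10% of 30 replicates

    def test_profile_ci_brackets_estimate(self):
        ped, truth = _simulate(a2=0.4, n_mz=150, n_dz=150, p_sib=0, n_single=0, seed=7)
        vc = fit_univariate(_theta_scores(truth), ped, model="AE", seed=0, ci=True)
        lo, hi = vc.ci_a2
        assert lo <= vc.a2 <= hi
        assert hi - lo < 0.5


class TestHomogeneity:
    def test_constrained_fit_never_beats_saturated(self):
        for rep in range(5):
            ped, truth = _simulate(seed=300 + rep, n_single=0)
            lrt, df, p = omnibus_homogeneity_test(_theta_scores(truth), ped)
            assert lrt >= 0
            assert df == 6  # 2 x 5 saturated params vs 2 + 2 constrained

    def test_null_p_values_uniform(self):
        ps = []
        for rep in range(120):
            ped, truth = _simulate(a2=0.4, n_mz=80, n_dz=80, p_sib=0,
                                   n_single=0, seed=400 + rep)
            _, _, p = omnibus_homogeneity_test(_theta_scores(truth), ped)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_inflated_group_variance_detected(self):
        hits = 0
        for rep in range(10):
            ped, truth = _simulate(a2=0.4, n_mz=300, n_dz=300, p_sib=0,
                                   n_single=0, seed=600 + rep)
            scores = _theta_scores(truth)
            mz1 = ped[(ped.zygosity == "MZ") & (ped.role == "twin1")]["person_id"]
            scores.loc[scores.person_id.isin(mz1), "score"] *= np.sqrt(2)
            _, _, p = omnibus_homogeneity_test(scores, ped)
            hits += p < 0.05
        assert hits >= 9


class TestSexLimitation:
    def test_equal_paths_never_fit_better_than_free(self):
        ped, truth = _simulate(seed=8, n_single=0)
        rep = sex_limitation_check(_theta_scores(truth), ped)
        assert rep["minus2ll_free"] <= rep["minus2ll_equal"] + 1e-6

    def test_null_rarely_significant(self):
        sig = 0
        for r in range(20):
            ped, truth = _simulate(a2=0.4, n_mz=150, n_dz=300, p_sib=0,
                                   n_single=0, seed=700 + r)
            rep = sex_limitation_check(_theta_scores(truth), ped)
            sig += rep["p"] < 0.05
        assert sig <= 3

    def test_sex_specific_heritability_detected(self):
        hits = 0
        for r in range(5):
            cfg = ts.make_config(n_mz_pairs=400, n_dz_pairs=400, p_extra_sib=0,
                                 n_singletons=0,
                                 trait_params=[(0.6, 0.0, 0.4), (0.6, 0.0, 0.4)],
                                 seed=800 + r)
            _, ped, truth = ts.simulate_cohort(cfg)
            scores = _theta_scores(truth)
            # males get an independent reshuffled genetic part: a2 ~ 0.2
            males = ped[ped.sex == "M"]["person_id"]
            rng = np.random.default_rng(r)
            noise = rng.standard_normal(len(scores))
            is_m = scores.person_id.isin(males).to_numpy()
            scores.loc[is_m, "score"] = (np.sqrt(0.33) * scores.loc[is_m, "score"]
                                         + np.sqrt(0.67) * noise[is_m])
            rep = sex_limitation_check(scores, ped)
            hits += rep["p"] < 0.05
        assert hits >= 4


class TestBivariate:
    def test_recovery_of_component_correlations(self):
        rgs, res_ = [], []
        for rep in range(5):
            cfg = ts.make_config(n_mz_pairs=300, n_dz_pairs=300, p_extra_sib=0.13,
                                 n_singletons=0,
                                 trait_params=[(0.41, 0.0, 0.59), (0.42, 0.0, 0.58)],
                                 rG=0.87, rE=0.44, seed=900 + rep)
            _, ped, truth = ts.simulate_cohort(cfg)
            scores = _theta_scores(truth, ("trait_0", "trait_1"), ("score_0", "score_1"))
            fit = fit_bivariate(scores, ped, model="AE",
                                trait_cols=("score_0", "score_1"), seed=rep)
            rgs.append(fit.rG)
            res_.append(fit.rE)
        assert np.mean(rgs) == pytest.approx(0.87, abs=0.08)
        assert np.mean(res_) == pytest.approx(0.44, abs=0.07)

    def test_phenotypic_correlation_decomposes_exactly(self):
        cfg = ts.make_config(n_mz_pairs=200, n_dz_pairs=200, p_extra_sib=0,
                             n_singletons=0, rG=0.8, rE=0.4, seed=1000)
        _, ped, truth = ts.simulate_cohort(cfg)
        scores = _theta_scores(truth, ("trait_0", "trait_1"), ("score_0", "score_1"))
        fit = fit_bivariate(scores, ped, model="AE",
                            trait_cols=("score_0", "score_1"), seed=0)
        reconstructed = (fit.rG * np.sqrt(fit.a2[0] * fit.a2[1])
                         + fit.rE * np.sqrt(fit.e2[0] * fit.e2[1]))
        assert fit.r_phenotypic == pytest.approx(reconstructed, abs=1e-6)

    def test_single_common_factor_gives_rg_one(self):
        cfg = ts.make_config(n_mz_pairs=250, n_dz_pairs=250, p_extra_sib=0,
                             n_singletons=0, rG=1.0, rE=0.0, seed=1100)
        _, ped, truth = ts.simulate_cohort(cfg)
        scores = _theta_scores(truth, ("trait_0", "trait_1"), ("score_0", "score_1"))
        fit = fit_bivariate(scores, ped, model="AE",
                            trait_cols=("score_0", "score_1"), seed=0, lrt=True)
        assert abs(fit.rG) > 0.9
        assert fit.p_rg_one > 0.05

    def test_independent_traits_give_rg_near_zero(self):
        cfg = ts.make_config(n_mz_pairs=250, n_dz_pairs=250, p_extra_sib=0,
                             n_singletons=0, rG=0.0, rE=0.0, seed=1200)
        _, ped, truth = ts.simulate_cohort(cfg)
        scores = _theta_scores(truth, ("trait_0", "trait_1"), ("score_0", "score_1"))
        fit = fit_bivariate(scores, ped, model="AE",
                            trait_cols=("score_0", "score_1"), seed=0, lrt=True)
        assert abs(fit.rG) < 0.25
        assert fit.p_rg_zero > 0.05
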