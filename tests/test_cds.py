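import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, truncnorm

from apexds.cds import (
    aic_select,
    encounter_rate_variance,
    fit_cds,
    gof_ks,
    horvitz_thompson,
)
from apexds.detection import effective_half_width
from apexds.errors import InsufficientDataError, ValidationError
from apexds.simulate import bear_scenario, simulate_survey
from apexds.tables import FitResult, SurveyDesign


def make_obs(distances, design, sizes=1):
    n = len(distances)
    t = design.transects["transect"]
    return pd.DataFrame({
        "transect": np.resize(t.to_numpy(), n),
        "distance": np.asarray(distances, dtype=float),
        "size": np.resize(np.asarray(sizes), n),
        "det1": 1,
        "det2": 0,
    })


def design_for(w=400.0, n_transects=10, length=10.0, area=None):
    t = pd.DataFrame({"transect": [f"t{i}" for i in range(n_transects)],
                      "length_km": length, "stratum": "all"})
    a = (w / 1000.0) * n_transects * length
    return SurveyDesign(t, w=w, area_km2=area or 4 * a)


def draw_half_normal(rng, sigma, w, n):
    """Exact half-normal-on-[0,w] distance draws (truncated normal folded)."""
    return truncnorm.rvs(0, w / sigma, scale=sigma, size=n, random_state=rng)


def grid_mle_half_normal(x, w, sigmas):
    """Independent 1-D grid-search MLE oracle for the half-normal scale."""
    best, best_ll = None, -np.inf
    for s in sigmas:
        mu = s * np.sqrt(2 * np.pi) * (norm.cdf(w / s) - 0.5)
        ll = np.sum(-0.5 * (x / s) ** 2) - len(x) * np.log(mu)
        if ll > best_ll:
            best, best_ll = s, ll
    return best


class TestFitCds:
    def test_half_normal_scale_recovery_vs_grid_oracle(self, rng):
        w, sigma = 400.0, 80.0
        x = draw_half_normal(rng, sigma, w, 1000)
        design = design_for(w)
        fit = fit_cds(make_obs(x, design), design, "half_normal",
                      left_truncation=0.0)
        sigma_hat = fit.spec.sigma1
        assert 72 <= sigma_hat <= 88
        oracle = grid_mle_half_normal(x, w, np.linspace(60, 110, 2001))
        assert sigma_hat == pytest.approx(oracle, abs=0.1)

    def test_uniform_distances_drive_flat_fit(self, rng):
        w = 400.0
        x = rng.uniform(0, w, 600)
        design = design_for(w)
        fit = fit_cds(make_obs(x, design), design, "half_normal",
                      left_truncation=0.0)
        mu = effective_half_width(fit.spec, w)
        assert mu >= 0.95 * w

    def test_two_piece_apex_recovery(self, rng):
        w, th, s1, s2 = 600.0, 110.0, 60.0, 150.0
        # rejection sampling from the two-piece density
        x = rng.uniform(0, w, 40000)
        g = np.where(x <= th, np.exp(-((x - th) ** 2) / (2 * s1 ** 2)),
                     np.exp(-((x - th) ** 2) / (2 * s2 ** 2)))
        x = x[rng.uniform(0, 1, x.size) < g][:800]
        assert len(x) == 800
        design = design_for(w)
        fit = fit_cds(make_obs(x, design), design, "two_piece_normal",
                      left_truncation=0.0)
        assert 95 <= fit.theta <= 125
        # coarse 3-D grid-search oracle agrees on the apex neighbourhood
        best, best_ll = None, -np.inf
        for tg in np.linspace(80, 140, 25):
            for s1g in np.linspace(40, 90, 11):
                for s2g in np.linspace(100, 220, 13):
                    mu = (s1g * np.sqrt(2 * np.pi) * (norm.cdf(tg / s1g) - 0.5)
                          + s2g * np.sqrt(2 * np.pi)
                          * (norm.cdf((w - tg) / s2g) - 0.5))
                    d = x - tg
                    sig = np.where(d <= 0, s1g, s2g)
                    ll = np.sum(-0.5 * (d / sig) ** 2) - len(x) * np.log(mu)
                    if ll > best_ll:
                        best, best_ll = tg, ll
        assert fit.theta == pytest.approx(best, abs=10.0)

    def test_insufficient_data(self, toy_design):
        with pytest.raises(InsufficientDataError):
            fit_cds(make_obs([100.0], toy_design), toy_design, "half_normal",
                    left_truncation=0.0)

    def test_small_sample_warns(self, toy_design, rng):
        x = draw_half_normal(rng, 80, 400.0, 30)
        with pytest.warns(UserWarning, match="60-80"):
            fit_cds(make_obs(x, toy_design), toy_design, "half_normal",
                    left_truncation=0.0)

    def test_left_truncation_shifts_and_shrinks_strip(self, rng):
        w, sigma = 400.0, 90.0
        x = draw_half_normal(rng, sigma, w, 800)
        design = design_for(w)
        t = 50.0
        fit = fit_cds(make_obs(x, design), design, "half_normal",
                      left_truncation=t)
        assert fit.left_truncation == t
        assert fit.n_obs == int(np.sum(x >= t))

    def test_auto_truncation_uses_two_piece_apex(self, rng):
        w, th, s1, s2 = 600.0, 110.0, 60.0, 150.0
        x = rng.uniform(0, w, 40000)
        g = np.where(x <= th, np.exp(-((x - th) ** 2) / (2 * s1 ** 2)),
                     np.exp(-((x - th) ** 2) / (2 * s2 ** 2)))
        x = x[rng.uniform(0, 1, x.size) < g][:800]
        design = design_for(w)
        fit = fit_cds(make_obs(x, design), design, "half_normal")  # auto
        assert 80 <= fit.left_truncation <= 140

    def test_abundance_invariant_to_distance_rescaling(self, rng):
        w = 400.0
        x = draw_half_normal(rng, 80, w, 500)
        d1 = design_for(w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_cds(make_obs(x, d1), d1, "half_normal", left_truncation=0.0)
            d2 = SurveyDesign(d1.transects, w=2 * w, area_km2=d1.area_km2 * 2)
            f2 = fit_cds(make_obs(2 * x, d2), d2, "half_normal",
                         left_truncation=0.0)
        # P_a = mu/w is scale-free; with A scaled like the covered area the
        # abundance estimate is unchanged
        assert f1.abundance == pytest.approx(f2.abundance, rel=1e-3)


class TestHorvitzThompson:
    def test_census_limit(self):
        n, g = horvitz_thompson([2, 1, 3], [1.0, 1.0, 1.0], 1.0)
        assert n == 6 and g == 3

    def test_hand_arithmetic(self):
        n, g = horvitz_thompson([2, 1], [0.5, 0.25], 10.0)
        assert n == pytest.approx(80.0)
        assert g == pytest.approx(60.0)

    def test_invalid_pa(self):
        with pytest.raises(ValidationError):
            horvitz_thompson([1], [0.0], 1.0)

    def test_monte_carlo_unbiasedness_with_perfect_apex(self):
        """Known N, certain apex detection: mean(N_hat)/N within 3%."""
        scn = bear_scenario(
            n_groups=1000,
            observer_logits=(12.0, -30.0),  # one perfect-at-apex observer
            heterogeneity_tau=0.0, beta=(), detection_covariates=(),
            draw_covariates=False)
        ratios = []
        seeds = np.random.SeedSequence(99).generate_state(300) % (2**31)
        for s in seeds:
            obs, design, truth = simulate_survey(scn, seed=int(s))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cds(obs, design, "two_piece_normal",
                              left_truncation=0.0, compute_vcov=False)
            ratios.append(fit.abundance / truth["n_individuals"])
        assert 0.97 <= np.mean(ratios) <= 1.03


class TestEncounterRateVariance:
    def test_hand_example(self, toy_design):
        obs = make_obs([10] * 10, toy_design)
        obs["transect"] = ["t1"] * 2 + ["t2"] * 3 + ["t3"] * 5
        er = encounter_rate_variance(obs, toy_design)
        assert er["var_rate"] == pytest.approx(0.046875)
        assert er["var_n"] == pytest.approx(0.046875 * 16)

    def test_zero_dispersion(self, toy_design):
        # rates 2/1, 2/1, 4/2 are identical
        obs = make_obs([10] * 8, toy_design)
        obs["transect"] = ["t1"] * 2 + ["t2"] * 2 + ["t3"] * 4
        er = encounter_rate_variance(obs, toy_design)
        assert er["var_rate"] == pytest.approx(0.0, abs=1e-15)

    def test_doubling_scaling_property(self, toy_design):
        obs = make_obs([10] * 10, toy_design)
        obs["transect"] = ["t1"] * 2 + ["t2"] * 3 + ["t3"] * 5
        base = encounter_rate_variance(obs, toy_design)
        t2 = toy_design.transects.copy()
        t2["length_km"] *= 2
        d2 = SurveyDesign(t2, toy_design.w, toy_design.area_km2)
        obs2 = pd.concat([obs, obs], ignore_index=True)
        doubled = encounter_rate_variance(obs2, d2)
        assert doubled["var_n"] == pytest.approx(4 * base["var_n"])
        assert doubled["n"] / doubled["L"] == pytest.approx(base["n"] / base["L"])

    def test_single_transect_directs_to_bootstrap(self):
        t = pd.DataFrame({"transect": ["only"], "length_km": [5.0]})
        d = SurveyDesign(t, 400.0, 10.0)
        with pytest.raises(InsufficientDataError, match="bootstrap"):
            encounter_rate_variance(make_obs([10.0, 20.0], d), d)

    def test_zero_count_transects_enter(self, toy_design):
        obs = make_obs([10.0, 20.0], toy_design)
        obs["transect"] = ["t1", "t1"]
        er = encounter_rate_variance(obs, toy_design)
        assert er["K"] == 3 and er["n"] == 2
        assert er["var_rate"] > 0


class TestGofKs:
    def test_hand_ecdf_arithmetic(self, toy_design):
        """PIT values (0.25, 0.5, 0.75) against uniform give D = 0.25."""
        flat = FitResult(
            spec=__import__("apexds").DetectionFunctionSpec("half_normal", 1e9),
            loglik=0.0, n_params=1, w=400.0, left_truncation=0.0)
        obs = make_obs([100.0, 200.0, 300.0], toy_design)
        d, p = gof_ks(flat, obs)
        assert d == pytest.approx(0.25)

    def test_calibration_under_true_model(self, rng):
        """Fitting the generating model: KS p-value rarely small."""
        w, sigma = 400.0, 90.0
        design = design_for(w)
        ok = 0
        for _ in range(100):
            x = draw_half_normal(rng, sigma, w, 500)
            fit = fit_cds(make_obs(x, design), design, "half_normal",
                          left_truncation=0.0, compute_abundance=False,
                          compute_vcov=False)
            _, p = gof_ks(fit, make_obs(x, design))
            ok += p > 0.01
        assert ok >= 95

    def test_misfit_detected_by_larger_D(self, rng):
        # strongly off-line-peaked data: half-normal misfits, two-piece fits
        w, th = 600.0, 200.0
        x = rng.uniform(0, w, 40000)
        g = np.where(x <= th, np.exp(-((x - th) ** 2) / (2 * 40.0 ** 2)),
                     np.exp(-((x - th) ** 2) / (2 * 120.0 ** 2)))
        x = x[rng.uniform(0, 1, x.size) < g][:600]
        design = design_for(w)
        obs = make_obs(x, design)
        hn = fit_cds(obs, design, "half_normal", left_truncation=0.0,
                     compute_abundance=False, compute_vcov=False)
        tp = fit_cds(obs, design, "two_piece_normal", left_truncation=0.0,
                     compute_abundance=False, compute_vcov=False)
        d_hn, _ = gof_ks(hn, obs)
        d_tp, _ = gof_ks(tp, obs)
        assert d_hn > d_tp


class TestAicSelect:
    def test_formula(self):
        f = FitResult(spec=None, loglik=-100.0, n_params=3)
        assert f.aic == pytest.approx(206.0)

    def test_tie_broken_by_fewer_parameters(self):
        a = FitResult(spec=None, loglik=-100.0, n_params=3)
        b = FitResult(spec=None, loglik=-101.0, n_params=1)
        b.loglik = -(a.aic - 2 * 1) / 2  # same AIC, fewer params
        ranked = aic_select([a, b])
        assert ranked[0] is b

    def test_incomparable_likelihoods_rejected(self):
        a = FitResult(spec=None, loglik=-100.0, n_params=3,
                      likelihood_type="distance")
        b = FitResult(spec=None, loglik=-90.0, n_params=5,
                      likelihood_type="distance+mr")
        with pytest.raises(ValidationError, match="not comparable"):
            aic_select([a, b])

    def test_differing_truncation_rejected(self):
        a = FitResult(spec=None, loglik=-1.0, n_params=1, left_truncation=0.0)
        b = FitResult(spec=None, loglik=-1.0, n_params=1, left_truncation=50.0)
        with pytest.raises(ValidationError):
            aic_select([a, b])

    def test_true_covariate_model_selected(self):
        """Nested recovery: AIC prefers the generating covariate model."""
        scn = bear_scenario(
            n_groups=1500, form="half_normal", sigma1=120.0, theta=0.0,
            observer_logits=(12.0, -30.0), heterogeneity_tau=0.0,
            beta=(-0.4,), detection_covariates=("cover",))
        wins = 0
        seeds = np.random.SeedSequence(123).generate_state(100) % (2**31)
        for s in seeds:
            obs, design, _ = simulate_survey(scn, seed=int(s))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                null = fit_cds(obs, design, "half_normal", left_truncation=0.0,
                               compute_abundance=False, compute_vcov=False)
                true = fit_cds(obs, design, "half_normal",
                               covariates=("cover",), left_truncation=0.0,
                               compute_abundance=False, compute_vcov=False)
            wins += aic_select([null, true])[0] is true
        assert wins >= 90
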