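import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

from apexds.errors import ValidationError
from apexds.simulate import (
    SimulationScenario,
    Stratum,
    bear_scenario,
    simulate_availability_series,
    simulate_stakes,
    simulate_survey,
    stake_curves,
    stakes_to_observations,
)


class TestSimulateSurvey:
    def test_same_seed_identical_outputs(self):
        scn = bear_scenario()
        o1, d1, t1 = simulate_survey(scn, seed=9)
        o2, d2, t2 = simulate_survey(scn, seed=9)
        pd.testing.assert_frame_equal(o1, o2)
        pd.testing.assert_frame_equal(t1["groups"], t2["groups"])
        assert t1["n_individuals"] == t2["n_individuals"]

    def test_different_seed_differs(self):
        scn = bear_scenario()
        o1, _, _ = simulate_survey(scn, seed=9)
        o2, _, _ = simulate_survey(scn, seed=10)
        assert not o1.equals(o2)

    def test_empty_population_gives_empty_survey(self):
        obs, design, truth = simulate_survey(bear_scenario(n_groups=0), seed=1)
        assert len(obs) == 0
        assert truth["n_detected"] == 0
        assert set(obs.columns) >= {"transect", "distance", "size",
                                    "det1", "det2"}

    def test_census_limit(self):
        """Certain detection, full coverage: every group is detected."""
        # one stratum whose strips tile the study area exactly
        scn = SimulationScenario(
            n_groups=300,
            strata=(Stratum("all", area_km2=0.4 * 40, n_transects=40,
                            transect_length_km=1.0),),
            w=400.0, form="half_normal", sigma1=1e9, theta=0.0,
            observer_logits=(40.0, 40.0), heterogeneity_tau=0.0,
            beta=(), detection_covariates=(), draw_covariates=False)
        obs, design, truth = simulate_survey(scn, seed=2)
        assert design.covered_area_km2 == pytest.approx(design.area_km2)
        assert len(obs) == truth["n_groups"] == 300

    def test_detection_count_matches_analytic_expectation(self):
        """Detected count within 3 binomial SDs of N * E[P_a] (quadrature
        plus Gauss-Hermite integration over the shared frailty)."""
        scn = bear_scenario(n_groups=4000, draw_covariates=True, seed=None)
        obs, design, truth = simulate_survey(scn, seed=123)
        th, s1, s2, w = scn.theta, scn.sigma1, scn.sigma2, scn.w
        tau = scn.heterogeneity_tau
        nodes, wts = np.polynomial.hermite_e.hermegauss(40)
        cover_probs = (0.4, 0.3, 0.2, 0.1)

        def pooled_mean(cov):
            mult = np.exp(scn.beta[0] * cov)

            def f(x):
                g = np.exp(-((x - th) ** 2)
                           / (2 * (np.where(x <= th, s1, s2) * mult) ** 2))
                acc = 0.0
                for e, wt in zip(nodes, wts):
                    p1 = expit(scn.observer_logits[0] + tau * e) * g
                    p2 = expit(scn.observer_logits[1] + tau * e) * g
                    acc += wt * (1 - (1 - p1) * (1 - p2))
                return acc / np.sqrt(2 * np.pi)

            val, _ = integrate.quad(f, 0, w, limit=200)
            return val / w

        e_pa = sum(p * pooled_mean(c) for c, p in enumerate(cover_probs))
        coverage = design.covered_area_km2 / design.area_km2
        expect = scn.n_groups * coverage * e_pa
        sd = np.sqrt(scn.n_groups * coverage * e_pa * (1 - e_pa))
        assert abs(len(obs) - expect) < 3 * sd

    def test_frailty_induces_between_observer_correlation(self):
        """tau > 0: positive odds ratio at fixed distance band; tau = 0: ~1."""

        def odds_ratio(tau, seed):
            scn = bear_scenario(n_groups=60000, heterogeneity_tau=tau,
                                beta=(), detection_covariates=(),
                                draw_covariates=False)
            _, _, truth = simulate_survey(scn, seed=seed)
            g = truth["groups"]
            g = g[g["covered"] & g["distance"].between(80, 140)]
            n11 = ((g["det1"] == 1) & (g["det2"] == 1)).sum()
            n10 = ((g["det1"] == 1) & (g["det2"] == 0)).sum()
            n01 = ((g["det1"] == 0) & (g["det2"] == 1)).sum()
            n00 = ((g["det1"] == 0) & (g["det2"] == 0)).sum()
            return (n11 * n00) / (n10 * n01)

        assert odds_ratio(1.5, 31) > 1.5
        assert odds_ratio(0.0, 32) == pytest.approx(1.0, abs=0.25)

    def test_availability_removes_groups(self):
        scn = bear_scenario(n_groups=30000, availability_psi=0.6,
                            draw_covariates=False, beta=(),
                            detection_covariates=())
        _, _, truth = simulate_survey(scn, seed=3)
        frac = truth["n_available"] / truth["n_groups"]
        assert frac == pytest.approx(0.6, abs=0.02)

    def test_hotspot_transects_attract_groups(self):
        scn = bear_scenario(n_groups=50000, hotspots=3,
                            hotspot_multiplier=10.0, draw_covariates=False,
                            beta=(), detection_covariates=())
        obs, design, truth = simulate_survey(scn, seed=4)
        counts = obs.groupby("transect").size().sort_values()
        # top transects should far exceed the median
        assert counts.iloc[-3:].min() > 3 * counts.median()

    def test_group_sizes_zero_truncated_with_target_mean(self):
        scn = bear_scenario(n_groups=50000, draw_covariates=False,
                            beta=(), detection_covariates=())
        _, _, truth = simulate_survey(scn, seed=5)
        sizes = truth["groups"]["size"]
        assert sizes.min() >= 1
        assert sizes.mean() == pytest.approx(1.6, abs=0.02)

    def test_stratum_density_multiplier(self):
        scn = bear_scenario(
            n_groups=40000,
            strata=(Stratum("a", 4000.0, 10, 10.0, density_multiplier=1.0),
                    Stratum("b", 4000.0, 10, 10.0, density_multiplier=3.0)),
            draw_covariates=False, beta=(), detection_covariates=())
        _, _, truth = simulate_survey(scn, seed=6)
        g = truth["groups"]
        ratio = (g["stratum"] == "b").sum() / (g["stratum"] == "a").sum()
        assert ratio == pytest.approx(3.0, abs=0.15)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValidationError):
            bear_scenario(availability_psi=0.0)
        with pytest.raises(ValidationError):
            bear_scenario(heterogeneity_tau=-1.0)
        with pytest.raises(ValidationError):
            bear_scenario(strata=())


class TestStakes:
    def test_certain_detection_sees_everything(self):
        curves = [{"apex_logit": 40.0, "sigma": 1e9} for _ in range(3)]
        stakes, design = simulate_stakes(100, 3, curves=curves,
                                         heterogeneity_tau=0.0,
                                         sigma_frailty_sd=0.0, seed=1)
        assert stakes[["det_1", "det_2", "det_3"]].to_numpy().all()

    def test_positions_shared_across_observers(self):
        stakes, _ = simulate_stakes(150, 8, seed=2)
        assert stakes["distance"].between(0, 20).all()
        assert len(stakes) == 150
        assert {f"det_{o}" for o in range(1, 9)} <= set(stakes.columns)

    def test_design_truth_is_n_stakes(self):
        _, design = simulate_stakes(150, 2, seed=3)
        assert design.area_km2 == pytest.approx(design.covered_area_km2)

    def test_conversion_to_double_observer_table(self):
        stakes, _ = simulate_stakes(150, 2, seed=4)
        obs = stakes_to_observations(stakes, 1, 2)
        assert ((obs["det1"] + obs["det2"]) >= 1).all()
        assert len(obs) <= 150

    def test_observer_spread(self, rng):
        curves = stake_curves(8, logit_spread=0.5, sigma_spread=3.0, rng=rng)
        logits = {c["apex_logit"] for c in curves}
        assert len(logits) == 8


class TestAvailabilitySeries:
    def test_always_available(self):
        scn = bear_scenario(n_groups=50, availability_psi=1.0)
        m = simulate_availability_series(scn, days=10, seed=1)
        assert m.shape == (50, 10)
        assert m.all()

    def test_iid_limit_no_autocorrelation(self):
        scn = bear_scenario(n_groups=5000, availability_psi=0.7,
                            availability_rho=0.0)
        m = simulate_availability_series(scn, days=40, seed=2)
        a = m[:, :-1].ravel().astype(float)
        b = m[:, 1:].ravel().astype(float)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_stationary_frequency_with_persistence(self):
        scn = bear_scenario(n_groups=10000, availability_psi=0.8,
                            availability_rho=0.6)
        m = simulate_availability_series(scn, days=50, seed=3)
        assert m.mean() == pytest.approx(0.8, abs=0.01)
        # and the persistence is visible as lag-1 correlation ~ rho
        a = m[:, :-1].ravel().astype(float)
        b = m[:, 1:].ravel().astype(float)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_invalid_inputs(self):
        scn = bear_scenario()
        with pytest.raises(ValidationError):
            simulate_availability_series(scn, days=0)
        with pytest.raises(ValidationError):
            simulate_availability_series(
                bear_scenario(availability_rho=1.0), days=2)
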