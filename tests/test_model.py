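import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conipheno import model, synth
from conipheno.model import ModelParams


def params(**kw):
    base = dict(
        theta1=5.0, theta2=0.0, rho1=0.002, rho2=0.003,
        d_switch=200.0, gamma_min=0.36, gamma_max=0.42, sigma=0.003,
    )
    base.update(kw)
    return ModelParams(**base)


def flat_weather(tmax, tmin, year=2019):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin})


class TestDeltaGamma:
    def test_spring_warm_day(self):
        assert model.delta_gamma(params(), tmax=10.0, tmin=2.0, doy=100) == pytest.approx(0.010)

    def test_spring_cold_day_clamped(self):
        assert model.delta_gamma(params(), tmax=4.0, tmin=-2.0, doy=100) == 0.0

    def test_autumn_cold_night(self):
        assert model.delta_gamma(params(), tmax=5.0, tmin=-5.0, doy=250) == pytest.approx(-0.015)

    def test_sign_structure(self):
        p = params()
        rng = np.random.default_rng(0)
        for _ in range(200):
            tmax, tmin = rng.uniform(-30, 35), rng.uniform(-40, 25)
            doy = rng.integers(1, 366)
            dg = model.delta_gamma(p, tmax, tmin, doy)
            if doy < int(p.d_switch):
                assert dg >= 0
            else:
                assert dg <= 0


class TestSimulateTrajectory:
    def test_no_forcing_constant(self):
        w = flat_weather(tmax=3.0, tmin=1.0)  # below theta1, above theta2
        traj = model.simulate_trajectory(params(), w, gamma_init=0.38)
        assert np.allclose(traj["gamma"], 0.38)

    def test_warm_spring_saturates_at_gamma_max(self):
        w = flat_weather(tmax=15.0, tmin=5.0)
        traj = model.simulate_trajectory(params(), w)
        doy = pd.to_datetime(traj["date"]).dt.dayofyear
        assert np.allclose(traj.loc[(doy > 50) & (doy < 199), "gamma"], 0.42)

    def test_hand_iterated_increments(self):
        # 5 warm days of +0.010 each from 0.36 with ceiling 0.42
        p = params(gamma_max=0.42)
        dates = pd.date_range("2019-03-01", periods=5, freq="D")
        w = pd.DataFrame({"date": dates, "tmax": 10.0, "tmin": 0.0})
        traj = model.simulate_trajectory(p, w, gamma_init=0.36)
        assert np.allclose(traj["gamma"], [0.37, 0.38, 0.39, 0.40, 0.41])

    def test_out_of_bounds_init_clamped(self):
        w = flat_weather(tmax=3.0, tmin=1.0)
        with pytest.warns(UserWarning):
            traj = model.simulate_trajectory(params(), w, gamma_init=0.9)
        assert traj["gamma"].iloc[0] == pytest.approx(0.42)

    def test_gap_in_weather_rejected(self):
        w = flat_weather(tmax=3.0, tmin=1.0).drop(index=100)
        with pytest.raises(ValueError):
            model.simulate_trajectory(params(), w)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_state_never_leaves_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = params(
            theta1=rng.uniform(-5, 10),
            theta2=rng.uniform(-10, 5),
            rho1=rng.uniform(0, 0.01),
            rho2=rng.uniform(0, 0.01),
            d_switch=rng.uniform(152, 274),
        )
        dates = pd.date_range("2018-01-01", periods=500, freq="D")
        w = pd.DataFrame(
            {
                "date": dates,
                "tmax": rng.normal(8, 12, 500),
            }
        )
        w["tmin"] = w["tmax"] - abs(rng.normal(8, 3, 500))
        traj = model.simulate_trajectory(p, w)
        assert (traj["gamma"] >= p.gamma_min - 1e-12).all()
        assert (traj["gamma"] <= p.gamma_max + 1e-12).all()


class TestLogLikelihood:
    def _obs_on_trajectory(self, p, w):
        traj = model.simulate_trajectory(p, w)
        return pd.DataFrame({"date": traj["date"], "gcc": traj["gamma"]})

    def test_zero_residual_closed_form(self):
        p = params()
        w = flat_weather(tmax=10.0, tmin=2.0)
        obs = self._obs_on_trajectory(p, w)
        n = len(obs)
        expected = n * np.log(1.0 / (p.sigma * np.sqrt(2 * np.pi)))
        assert model.log_likelihood(p, w, obs) == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma_zero_residuals(self):
        p = params()
        w = flat_weather(tmax=10.0, tmin=2.0)
        obs = self._obs_on_trajectory(p, w)
        n = len(obs)
        ll1 = model.log_likelihood(p, w, obs)
        ll2 = model.log_likelihood(params(sigma=2 * p.sigma), w, obs)
        assert ll1 - ll2 == pytest.approx(n * np.log(2), rel=1e-9)

    def test_matches_bruteforce_summation(self):
        from scipy.stats import norm

        p = params()
        rng = np.random.default_rng(7)
        w = flat_weather(tmax=12.0, tmin=-1.0)
        traj = model.simulate_trajectory(p, w)
        keep = rng.random(len(traj)) < 0.7
        obs = pd.DataFrame(
            {
                "date": traj.loc[keep, "date"],
                "gcc": traj.loc[keep, "gamma"] + rng.normal(0, 0.003, keep.sum()),
            }
        )
        brute = float(
            np.sum(norm.logpdf(obs["gcc"].to_numpy(),
                               loc=traj.loc[keep, "gamma"].to_numpy(), scale=p.sigma))
        )
        assert model.log_likelihood(p, w, obs) == pytest.approx(brute, abs=1e-9)

    def test_observation_outside_weather_rejected(self):
        p = params()
        w = flat_weather(tmax=10.0, tmin=2.0)
        obs = pd.DataFrame({"date": [pd.Timestamp("2030-01-01")], "gcc": [0.4]})
        with pytest.raises(ValueError):
            model.log_likelihood(p, w, obs)


class TestFitPosterior:
    def test_single_year_rejected(self, site_config):
        w = synth.generate_weather(site_config, 1)
        sim = synth.generate_greenness(site_config, w)
        with pytest.raises(ValueError):
            model.fit_posterior(w, sim.observations)

    def test_flat_observations_leave_d_switch_at_prior(self):
        """With no seasonality, the phase-switch day is unidentified and its
        posterior should essentially reproduce its uniform prior."""
        rng = np.random.default_rng(3)
        dates = pd.date_range("2018-01-01", "2020-12-31", freq="D")
        w = pd.DataFrame({"date": dates, "tmax": 3.0, "tmin": 1.0})
        obs = pd.DataFrame({"date": dates, "gcc": rng.normal(0.39, 0.003, len(dates))})
        fit = model.fit_posterior(
            w, obs, mcmc=model.MCMCConfig(seed=0, n_chains=2, n_iter=1000, n_warmup=1000)
        )
        d = fit.draws["d_switch"].to_numpy()
        # overlap coefficient between posterior histogram and the U(152, 274) prior
        hist, edges = np.histogram(d, bins=12, range=(152, 274), density=True)
        prior_density = 1.0 / (274 - 152)
        overlap = np.sum(np.minimum(hist, prior_density) * np.diff(edges))
        assert overlap > 0.8


class TestModelTransitions:
    def test_linear_ramp_midpoint(self):
        dates = pd.date_range("2019-01-01", "2019-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        gamma = np.interp(doy, [1, 100, 140, 365], [0.36, 0.36, 0.42, 0.42])
        traj = pd.DataFrame({"date": dates, "value": gamma})
        from conipheno.phenology import extract_transitions

        trans = extract_transitions(traj, thresholds=(0.5,))
        sos = trans[trans.direction == "rising"]["doy"].iloc[0]
        assert sos == pytest.approx(120.0, abs=0.5)

    def test_constant_trajectory_empty(self):
        w = flat_weather(tmax=3.0, tmin=1.0)
        with pytest.warns(UserWarning):
            trans = model.model_transitions(params(), w)
        assert trans.empty

    def test_self_consistency_with_generator_truth(self, site_config, weather_5yr,
                                                   greenness_5yr):
        trans = model.model_transitions(
            site_config.model_params, weather_5yr, thresholds=(0.5,)
        )
        truth = greenness_5yr.truth["transitions"]
        merged = trans.merge(
            truth[truth.threshold == 0.5],
            on=["year", "direction", "threshold"], suffixes=("", "_true"),
        )
        assert not merged.empty
        assert (merged["doy"] - merged["doy_true"]).abs().max() <= 1.0

    def test_warmer_springs_never_delay_sos(self, site_config, weather_5yr):
        base = model.model_transitions(site_config.model_params, weather_5yr,
                                       thresholds=(0.5,))
        warm = weather_5yr.copy()
        warm["tmax"] = warm["tmax"] + 2.0
        warm["tmin"] = warm["tmin"] + 2.0
        shifted = model.model_transitions(site_config.model_params, warm, thresholds=(0.5,))
        m = base.merge(shifted, on=["year", "direction", "threshold"],
                       suffixes=("_base", "_warm"))
        rising = m[m.direction == "rising"]
        assert (rising["doy_warm"] <= rising["doy_base"] + 1e-9).all()


class TestCrossValidate:
    def test_zero_noise_perfect_r2(self):
        cfg = synth.SyntheticSiteConfig(seed=9)
        cfg.model_params = params(sigma=1e-6)
        cfg.missing_prob = 0.0
        cfg.camera.snow_prob = 0.0
        w = synth.generate_weather(cfg, 4)
        sim = synth.generate_greenness(cfg, w)
        cv = model.cross_validate(
            w, sim.observations,
            mcmc=model.MCMCConfig(seed=0, n_chains=2, n_iter=800, n_warmup=800),
        )
        assert cv["r2"] > 0.999

    def test_two_years_rejected(self):
        cfg = synth.SyntheticSiteConfig(seed=9)
        w = synth.generate_weather(cfg, 2)
        sim = synth.generate_greenness(cfg, w)
        with pytest.raises(ValueError):
            model.cross_validate(w, sim.observations)

    def test_missing_final_year_weather_rejected(self, site_config, weather_5yr,
                                                 greenness_5yr):
        w = weather_5yr[pd.to_datetime(weather_5yr["date"]).dt.year < 2019]
        with pytest.raises(ValueError):
            model.cross_validate(w, greenness_5yr.observations)
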