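"""Hierarchical logistic model: design, closed forms, MCMC, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import expit

from fledgeline import phenology
from fledgeline.phenology import (
    FledglingPhenology,
    PosteriorDraws,
    Standardizer,
    elevational_delay,
    linear_predictor,
    log_likelihood,
    proportion_curve,
    standardize,
    t50_summary,
    t50_z,
    year_deviation_summary,
)


def _records(doy, elev, year, y):
    return pd.DataFrame(
        {"doy": doy, "elevation_m": elev, "year": year, "response": np.asarray(y, float)}
    )


class TestStandardize:
    def test_two_point_z(self):
        rec = _records([100, 200], [1500, 2200], [2015, 2016], [0, 1])
        design, std = standardize(rec)
        np.testing.assert_allclose(design.z_date, [-0.70710678, 0.70710678], atol=1e-8)
        assert design.z_date.mean() == pytest.approx(0, abs=1e-12)
        assert design.z_date.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_round_trip_identity(self, rng):
        doy = rng.integers(120, 240, size=50)
        rec = _records(doy, rng.uniform(1500, 2200, 50), 2015, rng.integers(0, 2, 50))
        design, std = standardize(rec)
        np.testing.assert_allclose(std.doy_from_z(std.z_doy(doy)), doy, atol=1e-12)
        np.testing.assert_allclose(std.doy_from_z(design.z_date), doy, atol=1e-9)

    def test_constant_covariate_errors(self):
        rec = _records([100, 200], [1800, 1800], [2015, 2015], [0, 1])
        with pytest.raises(ValueError):
            standardize(rec)

    def test_year_index_contiguous_with_mapping(self):
        rec = _records([100, 150, 200], [1500, 1800, 2200], [2020, 2013, 2020], [0, 1, 1])
        design, _ = standardize(rec)
        assert design.years == [2013, 2020]
        np.testing.assert_array_equal(design.year_index, [1, 0, 1])


class TestLinearPredictor:
    def test_zero_betas(self):
        assert linear_predictor((0, 0, 0, 0), 0.0, 0.3, -0.2) == 0.0

    def test_date_only(self):
        assert linear_predictor((0, 0, 1, 0), 0.0, 2.0, 0.0) == pytest.approx(2.0)

    def test_against_independent_evaluator(self):
        """Hand-expanded polynomial oracle for a specific parameter set."""
        b = (0.5, 0.2, 2.0, 0.3)
        d, e, t = 0.1, 1.0, -0.4
        oracle = b[0] + b[1] * e + b[2] * (t + d) + b[3] * (t + d) * e
        assert oracle == pytest.approx(0.01, abs=1e-12)
        assert linear_predictor(b, d, t, e) == pytest.approx(oracle, abs=1e-12)


class TestLogLikelihood:
    @pytest.fixture()
    def one_obs_design(self):
        def make(y):
            rec = _records([100, 200], [1500, 2200], [2015, 2015], [y, y])
            design, _ = standardize(rec)
            return design
        return make

    def test_eta_zero_is_log_half(self):
        rec = _records([100, 200], [1500, 2200], [2015, 2015], [1, 0])
        design, _ = standardize(rec)
        ll = log_likelihood((0, 0, 0, 0), [0.0], design)
        assert ll == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_extreme_eta_stable(self):
        """log(1 - logistic(eta)) at eta ~ +/-50 without underflow to -inf.

        Oracle: 30-digit evaluation of log(1/(1+exp(eta))) via sympy.
        """
        import sympy

        rec = _records([100, 200], [1500, 2200], [2015, 2015], [0, 0])
        design, _ = standardize(rec)
        b2 = 50 * np.sqrt(2)
        ll = log_likelihood((0, 0, b2, 0), [0.0], design)
        oracle = sum(
            float(sympy.log(1 / (1 + sympy.exp(sympy.Float(b2 * z, 30)))).evalf(30))
            for z in design.z_date
        )
        assert np.isfinite(ll)
        assert ll == pytest.approx(oracle, rel=1e-12)
        huge = log_likelihood((0, 0, 700 * np.sqrt(2), 0), [0.0], design)
        assert np.isfinite(huge)


class TestT50ClosedForm:
    def test_symmetric_logistic(self):
        assert t50_z((0, 0, 1, 0), 0.0, 0.0) == 0.0

    def test_displacement_shift(self):
        assert t50_z((1, 0, 1, 0), 0.25, 0.0) == pytest.approx(-1.25)

    def test_bisection_oracle_single(self):
        b = (0.5, 0.2, 2.0, 0.3)
        root = brentq(lambda t: linear_predictor(b, 0.0, t, 1.0), -10, 10)
        assert root == pytest.approx(-0.304348, abs=1e-6)
        assert t50_z(b, 0.0, 1.0) == pytest.approx(root, abs=1e-10)

    def test_bisection_oracle_100_random_sets(self, rng):
        """Closed form vs root-finding on 100 random parameter/elevation sets."""
        n_checked = 0
        while n_checked < 100:
            b = rng.normal(0, 2, size=4)
            ze = rng.uniform(-2, 2)
            denom = b[2] + b[3] * ze
            if abs(denom) < 0.1:
                continue  # zero-denominator contract tested separately
            root_closed = t50_z(b, 0.0, ze)
            if abs(root_closed) > 9:
                continue
            root_bisect = brentq(lambda t: linear_predictor(b, 0.0, t, ze), -10, 10)
            assert abs(root_closed - root_bisect) < 1e-6
            # self-consistency: p = 0.5 at the root
            assert expit(linear_predictor(b, 0.0, root_closed, ze)) == pytest.approx(
                0.5, abs=1e-10
            )
            n_checked += 1

    def test_zero_denominator_propagates_nonfinite(self):
        val = t50_z((1.0, 0.0, 0.0, 0.0), 0.0, 0.0)
        assert not np.isfinite(val)


def _degenerate_draws(t50_z_value=0.0, mean_doy=170.0, n=100, years=(2015,)):
    """All-identical posterior: beta0 = -t50_z*beta2, beta2 = 1."""
    table = pd.DataFrame(
        {
            "chain": 0,
            "iter": np.arange(n),
            "beta0": -t50_z_value,
            "beta1": 0.0,
            "beta2": 1.0,
            "beta3": 0.0,
            "sigma": 0.01,
        }
    )
    for y in years:
        table[f"d_{y}"] = 0.0
    std = Standardizer(mean_doy=mean_doy, sd_doy=30.0, mean_elev=1850.0, sd_elev=200.0)
    return PosteriorDraws(
        table=table, standardizer=std, years=list(years),
        diagnostics=pd.DataFrame({"parameter": [], "r_hat": []}),
    )


class TestSummaries:
    def test_degenerate_posterior_point_and_interval(self):
        draws = _degenerate_draws()
        out = t50_summary(draws, [1850.0])
        row = out.iloc[0]
        assert row["t50_doy"] == pytest.approx(170.0)
        assert row["ci_low"] == pytest.approx(170.0)
        assert row["ci_high"] == pytest.approx(170.0)

    def test_presentation_elevations_default(self):
        out = t50_summary(_degenerate_draws())
        assert list(out["elevation_m"]) == [1650.0, 1850.0, 2050.0]

    def test_delay_zero_when_elevation_drops_out(self):
        draws = _degenerate_draws()  # beta1 = beta3 = 0
        res = elevational_delay(draws, 1500, 2200)
        assert res["delay_days"] == pytest.approx(0.0)
        assert res["delay_days_per_100m"] == pytest.approx(0.0)

    def test_delay_antisymmetry(self, coal_tit_fit):
        _, _, draws = coal_tit_fit
        fwd = elevational_delay(draws, 1650, 2050)
        with pytest.raises(ValueError):
            elevational_delay(draws, 2050, 1650)
        # antisymmetry via the per-draw definition
        diff_ab = draws.t50_doy(2050) - draws.t50_doy(1650)
        diff_ba = draws.t50_doy(1650) - draws.t50_doy(2050)
        np.testing.assert_allclose(diff_ab, -diff_ba, atol=1e-12)
        assert fwd["delay_days"] == pytest.approx(np.mean(diff_ab))

    def test_year_deviation_zero_and_scale(self):
        draws = _degenerate_draws(years=(2015,))
        out = year_deviation_summary(draws)
        assert out["deviation_days"].iloc[0] == pytest.approx(0.0)
        # d = +0.1 on the z-date scale with sd_doy = 30 -> -3.0 days
        draws.table["d_2015"] = 0.1
        out = year_deviation_summary(draws)
        assert out["deviation_days"].iloc[0] == pytest.approx(-3.0)

    def test_nonfinite_policy_small_fraction_excluded(self):
        draws = _degenerate_draws(n=200)
        draws.table.loc[0, "beta2"] = 0.0  # one zero-denominator draw (0.5%)
        out = t50_summary(draws, [1850.0])
        assert out["n_nonfinite"].iloc[0] == 1
        assert np.isfinite(out["t50_doy"].iloc[0])

    def test_nonfinite_policy_large_fraction_propagates(self):
        draws = _degenerate_draws(n=100)
        draws.table.loc[:9, "beta2"] = 0.0  # 10% non-finite: no trimming
        out = t50_summary(draws, [1850.0])
        assert out["n_nonfinite"].iloc[0] == 10
        assert not np.isfinite(out["ci_high"].iloc[0])


class TestProportionCurve:
    def test_half_at_t50_and_monotone(self, coal_tit_fit):
        _, _, draws = coal_tit_fit
        grid = np.linspace(120, 240, 200)
        curve = proportion_curve(draws, 1850.0, grid)
        assert curve["p_median"].is_monotonic_increasing
        assert ((curve["p_low"] <= curve["p_median"]) & (curve["p_median"] <= curve["p_high"])).all()
        # median curve crosses 0.5 near the posterior median t50
        t50_med = np.median(draws.t50_doy(1850.0))
        crossing = grid[np.argmin(np.abs(curve["p_median"] - 0.5))]
        assert abs(crossing - t50_med) < 1.5

    def test_limits(self):
        draws = _degenerate_draws()
        curve = proportion_curve(draws, 1850.0, np.array([-1e4, 1e4]))
        assert curve["p_median"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert curve["p_median"].iloc[1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_per_draw_when_slope_positive(self, coal_tit_fit):
        _, _, draws = coal_tit_fit
        std = draws.standardizer
        ze = float(std.z_elev(1850.0))
        b = draws.betas()
        pos = b[:, 2] + b[:, 3] * ze > 0
        zt = std.z_doy(np.array([130.0, 160.0, 190.0, 220.0]))
        eta = b[:, [0]] + b[:, [1]] * ze + (b[:, [2]] + b[:, [3]] * ze) * zt[None, :]
        p = expit(eta[pos])
        assert (np.diff(p, axis=1) >= 0).all()


class TestFit:
    def test_retained_draw_count_exact(self, coal_tit_fit):
        _, _, draws = coal_tit_fit
        assert draws.n_draws == 4 * 800 // 2
        assert set(draws.table["chain"]) == {0, 1, 2, 3}

    def test_t50_recovery_within_2_days(self, coal_tit_fit):
        truth, sidecar, draws = coal_tit_fit
        est = t50_summary(draws, [1650.0]).iloc[0]["t50_doy"]
        assert abs(est - truth.t50_doy(1650.0)) < 2.0

    def test_true_delay_inside_interval(self, coal_tit_fit):
        """Elevational delay (standardizer-invariant) is recovered."""
        truth, _, draws = coal_tit_fit
        res = elevational_delay(draws, 1650.0, 2050.0)
        true_delay = truth.t50_doy(2050.0) - truth.t50_doy(1650.0)
        assert res["ci_low"] <= true_delay <= res["ci_high"]
        # and per-100m scaling is consistent with the day total
        assert res["delay_days_per_100m"] == pytest.approx(res["delay_days"] / 4.0)

    def test_year_displacement_recovery(self):
        """A year shifted +2 days is recovered inside its interval."""
        from fledgeline.simulate import PhenologyTruth, simulate_observations
        from fledgeline import atlas

        truth = PhenologyTruth.from_natural(sigma_days=2.0)
        years = list(range(2013, 2023))
        d_days = {y: 0.0 for y in years}
        d_days[2013] = 2.0
        obs, _ = simulate_observations(truth, 4000, years, seed=99, d_year_days=d_days)
        enc, _ = atlas.encode_responses(obs)
        draws = phenology.fit_posterior(
            enc.dropna(subset=["response"]), chains=4, iterations=600, seed=3
        )
        dev = year_deviation_summary(draws).set_index("year")
        assert dev.loc[2013, "ci_low"] <= 2.0 <= dev.loc[2013, "ci_high"]

    def test_single_year_dataset_completes(self, rng):
        """Sigma is weakly identified with one year; the fit still completes."""
        from fledgeline.simulate import PhenologyTruth, simulate_observations
        from fledgeline import atlas

        truth = PhenologyTruth.from_natural(sigma_days=0.0)
        obs, _ = simulate_observations(truth, 400, [2015], seed=17)
        enc, _ = atlas.encode_responses(obs)
        draws = phenology.fit_posterior(
            enc.dropna(subset=["response"]), chains=2, iterations=400, seed=5
        )
        assert draws.n_draws == 2 * 200
        assert (draws.table["sigma"] > 0).all()

    def test_binary_response_validated(self):
        rec = _records([100, 200], [1500, 2200], [2015, 2015], [0, 2])
        with pytest.raises(ValueError):
            FledglingPhenology(iterations=10).fit(rec)

    def test_serialization_round_trip(self, coal_tit_fit, tmp_path):
        _, _, draws = coal_tit_fit
        draws.save(tmp_path / "fit")
        loaded = PosteriorDraws.load(tmp_path / "fit")
        pd.testing.assert_frame_equal(
            loaded.table, draws.table, check_exact=False, rtol=1e-12
        )
        assert loaded.years == draws.years
        assert loaded.standardizer.mean_doy == pytest.approx(draws.standardizer.mean_doy)
        np.testing.assert_allclose(
            loaded.t50_doy(1850.0), draws.t50_doy(1850.0), rtol=1e-9
        )

    def test_sklearn_params_contract(self):
        model = FledglingPhenology(chains=2, iterations=100)
        params = model.get_params()
        assert params["chains"] == 2
        clone = FledglingPhenology(**params)
        assert clone.get_params() == params
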