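"""Estimator correctness: tau fits, eta / eta_m round trips, mass bookkeeping."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from photherm.efficiency import (
    BeamGeometry,
    EquilibriumWarning,
    FitError,
    benchmark_ranking,
    concentration_from_extinction,
    estimate_eta,
    estimate_eta_m,
    eta_from_eta_m,
    fit_time_constant,
    mass_extinction_coefficient,
    mass_in_beam,
    transmission_fraction,
)
from photherm.particles import preset_suspension
from photherm.traces import TraceGenConfig, simulate_blank_trace, simulate_trace

import pandas as pd

AUNR_MASS_IN_BEAM_UG = 0.1 / 46.1 * 0.081 * 1e3  # = 0.176 ug


def make_trace(**kwargs):
    return simulate_trace(TraceGenConfig(**kwargs))


class TestTransmission:
    @pytest.mark.parametrize("eps,expected", [(0.1, 0.7943), (0.0, 1.0), (1.0, 0.1)])
    def test_decadic_transmission(self, eps, expected):
        assert transmission_fraction(eps) == pytest.approx(expected, abs=5e-5)

    def test_negative_extinction_rejected(self):
        with pytest.raises(ValueError):
            transmission_fraction(-0.1)


class TestMassExtinction:
    def test_benchmark_nanoshell_coefficient(self):
        # C chosen so that eps = 0.1 in a 1 cm cuvette reproduces 31.7 cm^2/mg
        assert mass_extinction_coefficient(0.1, 0.003155, 1.0) == pytest.approx(31.7, rel=1e-3)

    def test_zero_extinction_gives_zero(self):
        assert mass_extinction_coefficient(0.0, 0.01, 1.0) == 0.0

    def test_doubling_concentration_halves_coefficient(self):
        a = mass_extinction_coefficient(0.1, 0.002, 1.0)
        b = mass_extinction_coefficient(0.1, 0.004, 1.0)
        assert a == pytest.approx(2 * b)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            mass_extinction_coefficient(0.1, 0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        eps=st.floats(1e-6, 10.0),
        conc=st.floats(1e-9, 10.0),
        path=st.floats(1e-3, 100.0),
    )
    def test_coefficient_and_concentration_are_mutual_inverses(self, eps, conc, path):
        eps_m = mass_extinction_coefficient(eps, conc, path)
        back = concentration_from_extinction(eps, eps_m, path)
        assert back == pytest.approx(conc, rel=1e-12)


class TestTimeConstantFit:
    @pytest.mark.parametrize("tau", [300.0, 600.0, 1200.0])
    def test_exact_exponential_recovered(self, tau):
        trace = make_trace(tau_s=tau, heat_duration_s=10 * tau, cool_duration_s=4 * tau)
        fit = fit_time_constant(trace)
        assert fit.tau_s == pytest.approx(tau, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_unbiased_and_matches_nonlinear_oracle(self):
        """Median over seeds within 2% of tau=600 and close to a nonlinear fit."""
        lin, nonlin = [], []
        for seed in range(30):
            trace = make_trace(noise_sd_C=0.05, cool_duration_s=1200.0, seed=seed)
            lin.append(fit_time_constant(trace).tau_s)
            t, temp = trace.cooling_segment()
            popt, _ = curve_fit(
                lambda t, dT, tau: 25.0 + dT * np.exp(-t / tau),
                t, temp, p0=(8.0, 500.0),
            )
            nonlin.append(popt[1])
        assert np.median(lin) == pytest.approx(600.0, rel=0.02)
        assert np.median(np.abs(np.array(lin) / np.array(nonlin) - 1)) < 0.02

    def test_flat_trace_raises(self):
        trace = make_trace(eta_true=0.0, q_blank_W=0.0, heat_duration_s=100, cool_duration_s=100)
        with pytest.raises(FitError):
            fit_time_constant(trace)


class TestEstimateEta:
    @pytest.mark.parametrize("eta", [0.66, 0.20])
    def test_noiseless_round_trip(self, eta):
        trace = make_trace(eta_true=eta)
        assert estimate_eta(trace, None, 1.0, 0.1) == pytest.approx(eta, abs=1e-3)

    def test_round_trip_with_blank_correction(self):
        cfg = TraceGenConfig(q_blank_W=0.01)
        trace = simulate_trace(cfg)
        blank = simulate_blank_trace(cfg)
        assert estimate_eta(trace, blank, 1.0, 0.1) == pytest.approx(0.66, abs=1e-3)

    def test_sample_identical_to_blank_gives_zero(self):
        cfg = TraceGenConfig(eta_true=0.0, q_blank_W=0.01)
        trace = simulate_trace(cfg)
        blank = simulate_blank_trace(cfg)
        assert estimate_eta(trace, blank, 1.0, 0.1) == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_ambient_offset(self):
        a = estimate_eta(make_trace(t_ambient_C=25.0), None, 1.0, 0.1)
        b = estimate_eta(make_trace(t_ambient_C=32.5), None, 1.0, 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_warns_when_not_equilibrated(self):
        trace = make_trace(heat_duration_s=900.0)  # only 1.5 tau of heating
        with pytest.warns(EquilibriumWarning):
            estimate_eta(trace, None, 1.0, 0.1)

    def test_zero_extinction_rejected(self):
        with pytest.raises(ValueError):
            estimate_eta(make_trace(), None, 1.0, 0.0)

    @pytest.mark.parametrize("eta_true", [0.2, 0.34, 0.66])
    @pytest.mark.parametrize("tau", [300.0, 600.0, 1200.0])
    def test_recovery_grid_noiseless(self, eta_true, tau):
        trace = make_trace(eta_true=eta_true, tau_s=tau,
                           heat_duration_s=10 * tau, cool_duration_s=4 * tau)
        est = estimate_eta(trace, None, 1.0, 0.1)
        assert est == pytest.approx(eta_true, rel=0.02)

    @pytest.mark.parametrize("eta_true", [0.2, 0.34, 0.66])
    @pytest.mark.parametrize("tau", [300.0, 600.0, 1200.0])
    def test_recovery_grid_noisy_median(self, eta_true, tau):
        """Median recovery error over 50 seeds below 5% at 0.05 C noise."""
        ests = []
        for seed in range(50):
            trace = make_trace(
                eta_true=eta_true, tau_s=tau, noise_sd_C=0.05, seed=seed,
                heat_duration_s=10 * tau, cool_duration_s=4 * tau,
            )
            ests.append(estimate_eta(trace, None, 1.0, 0.1))
        assert np.median(np.abs(np.array(ests) / eta_true - 1)) < 0.05


class TestMassInBeam:
    def test_aunr_column_mass(self):
        c = preset_suspension("AuNR").mass_concentration_mg_per_mL
        m = mass_in_beam(c, BeamGeometry(area_cm2=0.081), 1.0)
        assert m == pytest.approx(0.176, abs=5e-4)

    def test_zero_concentration(self):
        assert mass_in_beam(0.0, BeamGeometry(), 1.0) == 0.0

    def test_linear_in_area(self):
        a = mass_in_beam(0.002, BeamGeometry(area_cm2=0.081), 1.0)
        b = mass_in_beam(0.002, BeamGeometry(area_cm2=0.162), 1.0)
        assert b == pytest.approx(2 * a)


class TestEtaM:
    def test_negligible_loss_limit_matches_closed_form(self):
        """With tau -> inf, eta_m = eta (1 - 10^-eps) / m_NPs = 0.771 /ug for AuNRs."""
        trace = make_trace(tau_s=1e7, heat_duration_s=600.0, cool_duration_s=0.0)
        est = estimate_eta_m(trace, None, 1.0, AUNR_MASS_IN_BEAM_UG)
        expected = 0.66 * (1 - 10**-0.1) / AUNR_MASS_IN_BEAM_UG
        assert expected == pytest.approx(0.771, abs=2e-3)
        assert est == pytest.approx(expected, rel=1e-3)

    def test_trace_equal_to_blank_gives_zero(self):
        cfg = TraceGenConfig(eta_true=0.0, q_blank_W=0.01)
        trace = simulate_trace(cfg)
        blank = simulate_blank_trace(cfg)
        assert estimate_eta_m(trace, blank, 1.0, 0.176) == pytest.approx(0.0, abs=1e-9)

    def test_inverse_proportional_to_mass(self):
        trace = make_trace(tau_s=1e7, heat_duration_s=600.0, cool_duration_s=0.0)
        a = estimate_eta_m(trace, None, 1.0, 0.176)
        b = estimate_eta_m(trace, None, 1.0, 0.088)
        assert b == pytest.approx(2 * a, rel=1e-9)

    def test_window_longer_than_heating_rejected(self):
        trace = make_trace(heat_duration_s=30.0, cool_duration_s=30.0)
        with pytest.raises(ValueError):
            estimate_eta_m(trace, None, 1.0, 0.176, window_s=60.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            estimate_eta_m(make_trace(), None, 1.0, 0.0)


class TestEtaFromEtaM:
    def test_inverts_the_closed_form(self):
        assert eta_from_eta_m(0.771, 0.176, 0.1) == pytest.approx(0.66, abs=2e-3)

    def test_zero_eta_m(self):
        assert eta_from_eta_m(0.0, 0.176, 0.1) == 0.0

    def test_zero_extinction_rejected(self):
        with pytest.raises(ValueError):
            eta_from_eta_m(0.771, 0.176, 0.0)

    def test_cross_method_consistency_at_finite_tau(self):
        """eta via the short-time eta_m route agrees with the equilibrium
        route within 3% on the same noiseless traces (tau = 600 s)."""
        cfg = TraceGenConfig(q_blank_W=0.01)
        trace = simulate_trace(cfg)
        blank = simulate_blank_trace(cfg)
        eta_eq = estimate_eta(trace, blank, 1.0, 0.1)
        eta_m = estimate_eta_m(trace, blank, 1.0, AUNR_MASS_IN_BEAM_UG)
        eta_st = eta_from_eta_m(eta_m, AUNR_MASS_IN_BEAM_UG, 0.1)
        assert eta_st == pytest.approx(eta_eq, rel=0.03)


class TestBenchmarkRanking:
    @staticmethod
    def preset_table():
        rows = []
        for name in ("AuNShell", "AuNR", "AuNStar"):
            s = preset_suspension(name)
            m_np = mass_in_beam(s.mass_concentration_mg_per_mL, BeamGeometry(), 1.0)
            eta_m = s.reference_eta * (1 - transmission_fraction(0.1)) / m_np
            rows.append({"name": name, "eta": s.reference_eta, "eta_m_per_ug": eta_m})
        return pd.DataFrame(rows)

    def test_reported_pairwise_reductions(self):
        tables = benchmark_ranking(self.preset_table())
        assert tables["ranking"]["name"].iloc[0] == "AuNR"
        eta_red = tables["eta_reduction_pct"].loc["AuNStar", "AuNR"]
        eta_m_red = tables["eta_m_reduction_pct"].loc["AuNStar", "AuNR"]
        assert eta_red == pytest.approx(48.0, abs=1.0)
        assert eta_m_red == pytest.approx(73.0, abs=1.5)

    def test_identical_entries_give_zero_difference(self):
        df = pd.DataFrame(
            {"name": ["a", "b"], "eta": [0.5, 0.5], "eta_m_per_ug": [0.3, 0.3]}
        )
        tables = benchmark_ranking(df)
        assert float(tables["eta_m_reduction_pct"].to_numpy().max()) == 0.0

    def test_single_entry_rejected(self):
        df = pd.DataFrame({"name": ["a"], "eta": [0.5], "eta_m_per_ug": [0.3]})
        with pytest.raises(ValueError):
            benchmark_ranking(df)
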