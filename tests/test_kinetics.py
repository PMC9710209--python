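"""Trace normalization, elongation and generalized-logistic fitting."""

import numpy as np
import pytest

from oligoflux import (
    DegenerateControlError,
    DegenerateTraceError,
    ElongationFit,
    InvalidInputError,
    KineticGroundTruth,
    ThTTrace,
    amplification_rate,
    fit_elongation,
    fit_logistic,
    gen_tht_traces,
    half_time,
    normalize_trace,
    relative_amplification,
    relative_elongation,
)
from oligoflux.kinetics import (
    amplification_at_half_time,
    fibril_mass,
    fibril_number,
    monomer_fraction,
    primary_nucleation_combination,
)
from oligoflux.synthetic import default_time_grid, gen_elongation_traces

from .conftest import make_fit


class TestNormalizeTrace:
    def test_linear_ramp_maps_to_unit_interval(self):
        t = np.arange(0.0, 100.0)
        raw = ThTTrace(time=t, signal=10.0 + t, normalized=False)
        out = normalize_trace(raw)
        assert out.normalized
        assert out.signal[0] == pytest.approx(0.0, abs=0.02)
        assert out.signal[-1] == pytest.approx(1.0, abs=0.03)

    def test_renormalizing_an_ideal_trace_changes_nothing(self):
        t = np.arange(0.0, 50.0)
        raw = ThTTrace(time=t, signal=5.0 + 3.0 / (1.0 + np.exp(-(t - 20.0) / 3.0)))
        once = normalize_trace(raw)
        again = normalize_trace(
            ThTTrace(time=once.time, signal=once.signal, normalized=False)
        )
        np.testing.assert_allclose(again.signal, once.signal, atol=1e-12)

    def test_raw_generator_output_round_trips_to_the_logistic(self, t_grid):
        truth = KineticGroundTruth(noise_sd=0.02, n_replicates=1, seed=5)
        raw = gen_tht_traces(t_grid=t_grid, truth=truth, raw_baseline=500.0,
                             raw_gain=2000.0)[0]
        assert not raw.normalized
        out = normalize_trace(raw)
        clean = fibril_mass(t_grid, truth.a, truth.kappa, truth.c)
        rms = np.sqrt(np.mean((out.signal - clean) ** 2))
        assert rms < 1.5 * truth.noise_sd

    def test_flat_trace_is_degenerate(self):
        t = np.arange(0.0, 20.0)
        with pytest.raises(DegenerateTraceError):
            normalize_trace(ThTTrace(time=t, signal=np.full_like(t, 7.0)))

    def test_already_normalized_input_is_rejected(self):
        t = np.arange(0.0, 20.0)
        tr = ThTTrace(time=t, signal=np.linspace(0, 1, t.size), normalized=True)
        with pytest.raises(InvalidInputError):
            normalize_trace(tr)


class TestElongationFit:
    def test_exact_line_recovers_slope_at_machine_precision(self):
        t = np.arange(0.0, 30.0)
        tr = ThTTrace(time=t, signal=0.003 * t, normalized=True)
        fit = fit_elongation(tr, n_points=6)
        assert fit.slope == pytest.approx(0.003, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points_used == 6

    def test_flat_trace_has_zero_slope(self):
        t = np.arange(0.0, 30.0)
        tr = ThTTrace(time=t, signal=np.full_like(t, 0.5), normalized=True)
        assert fit_elongation(tr).slope == pytest.approx(0.0, abs=1e-15)

    def test_window_of_fewer_than_two_points_is_invalid(self):
        t = np.arange(0.0, 30.0)
        tr = ThTTrace(time=t, signal=0.01 * t, normalized=True)
        with pytest.raises(InvalidInputError):
            fit_elongation(tr, n_points=1)

    def test_unnormalized_trace_is_rejected(self):
        t = np.arange(0.0, 30.0)
        with pytest.raises(InvalidInputError):
            fit_elongation(ThTTrace(time=t, signal=100 + t))

    def test_noisy_recovery_stays_within_its_sampling_error(self):
        # OLS slope s.e. on 6 unit-spaced points is noise_sd / sqrt(17.5)
        noise_sd, slope = 0.005, 0.002
        sigma = noise_sd / np.sqrt(17.5)
        for seed in range(10):
            tr = gen_elongation_traces(
                slope=slope, noise_sd=noise_sd, n_replicates=1, seed=seed
            )[0]
            assert abs(fit_elongation(tr).slope - slope) < 3 * sigma


class TestRelativeElongation:
    def test_arithmetic_and_control_identity(self):
        fits = {
            "A": ElongationFit(0.001, 0.0, 6, 1.0),
            "control": ElongationFit(0.002, 0.0, 6, 1.0),
        }
        rel = relative_elongation(fits)
        assert rel["A"][0] == pytest.approx(0.5)
        assert rel["control"][0] == pytest.approx(1.0)

    def test_control_replicates_average_exactly_one(self):
        fits = {
            "control": [
                ElongationFit(s, 0.0, 6, 1.0) for s in (0.0018, 0.0021, 0.0024)
            ]
        }
        rel = relative_elongation(fits)
        assert np.mean(rel["control"]) == pytest.approx(1.0, rel=1e-15)

    def test_nonpositive_control_is_degenerate(self):
        fits = {"control": ElongationFit(0.0, 0.0, 6, 1.0)}
        with pytest.raises(DegenerateControlError):
            relative_elongation(fits)


class TestLogisticFit:
    def test_noiseless_self_consistency_to_optimizer_tolerance(self, t_grid):
        truth = KineticGroundTruth(noise_sd=0.0, n_replicates=1)
        fit = fit_logistic(gen_tht_traces(truth, t_grid))
        assert fit.converged
        assert fit.a == pytest.approx(50.0, rel=1e-6)
        assert fit.kappa == pytest.approx(0.02, rel=1e-6)
        assert fit.c == 0.3
        assert fit.lambda_ == pytest.approx(0.02 * np.sqrt(2 / 50.0), rel=1e-6)

    def test_pooled_replicates_fit_is_close_under_noise(self, t_grid):
        truth = KineticGroundTruth(noise_sd=0.02, n_replicates=3, seed=1)
        fit = fit_logistic(gen_tht_traces(truth, t_grid))
        assert fit.converged
        assert fit.kappa == pytest.approx(0.02, rel=0.1)
        assert 0 < fit.rss
        assert fit.r_squared > 0.99

    def test_trace_stuck_below_plateau_yields_failure_result_not_crash(self):
        t = default_time_grid(500.0, 5.0)
        sig = 0.15 * (1 - np.exp(-t / 400.0))  # never exceeds 0.2 of plateau
        tr = ThTTrace(time=t, signal=sig, normalized=True)
        fit = fit_logistic(tr)
        assert not fit.converged
        assert fit.message

    def test_too_few_samples_rejected(self):
        t = np.arange(0.0, 8.0)
        tr = ThTTrace(time=t, signal=np.linspace(0, 1, t.size), normalized=True)
        with pytest.raises(InvalidInputError):
            fit_logistic(tr)


class TestHalfTime:
    def test_symmetric_special_case_matches_the_analytic_midpoint(self):
        # c = 1 reduces to the plain logistic with midpoint ln(a)/kappa
        fit = make_fit(a=80.0, kappa=0.01, c=1.0)
        assert half_time(fit) == pytest.approx(np.log(80.0) / 0.01, rel=1e-10)

    def test_half_time_decreases_when_kappa_doubles(self):
        t1 = half_time(make_fit(50.0, 0.02))
        t2 = half_time(make_fit(50.0, 0.04))
        assert t2 < t1

    def test_half_time_matches_a_dense_grid_crossing(self, canonical_fit):
        th = half_time(canonical_fit)
        t = np.arange(0.0, 1000.0, 0.01)
        M = fibril_mass(t, 50.0, 0.02, 0.3)
        crossing = t[np.searchsorted(M, 0.5)]
        assert abs(th - crossing) <= 0.01

    def test_invariance_under_time_unit_rescaling(self):
        minutes = half_time(make_fit(50.0, 0.02))
        hours = half_time(make_fit(50.0, 0.02 * 60.0))
        assert hours * 60.0 == pytest.approx(minutes, rel=1e-10)


class TestAmplificationRate:
    def test_finite_difference_oracle_on_the_canonical_parameters(self):
        a, kap, c, r = 50.0, 0.02, 0.3, 0.002
        fit = make_fit(a, kap, c)
        th = half_time(fit)
        t = np.arange(max(0.0, th - 5.0), th + 5.0, 1e-3)
        P = fibril_number(t, a, kap, c, r)
        dP = np.gradient(P, t)
        i = np.argmin(np.abs(t - th))
        closed = amplification_at_half_time(a, kap, c, r)
        assert closed == pytest.approx(dP[i], rel=5e-3)

    def test_no_growth_limit_vanishes(self):
        assert amplification_at_half_time(50.0, 1e-9, 0.3, 1.0) < 1e-15

    def test_control_normalization_identity(self):
        fits = [make_fit(a, 0.02) for a in (40.0, 50.0, 60.0)]
        rates = {"control": [amplification_rate(f, r_plus=0.002) for f in fits]}
        rel = relative_amplification(rates)
        assert np.mean(rel["control"]) == pytest.approx(1.0, rel=1e-15)


class TestModelFunctions:
    def test_monomer_plus_fibril_mass_is_unity(self):
        t = np.linspace(0, 500, 101)
        M = fibril_mass(t, 50.0, 0.02, 0.3)
        m = monomer_fraction(t, 50.0, 0.02, 0.3)
        np.testing.assert_allclose(M + m, 1.0, atol=1e-12)

    def test_lambda_matches_the_early_time_amplitude(self):
        # early-time limit: M(t) ~ (lambda^2 / 2 kappa^2) e^{kappa t}
        a, kap = 500.0, 0.01
        lam = primary_nucleation_combination(a, kap)
        t = np.array([1.0])
        early = (lam**2 / (2 * kap**2)) * np.exp(kap * t)
        assert fibril_mass(t, a, kap, 0.3)[0] == pytest.approx(
            early[0], rel=5e-3
        )
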