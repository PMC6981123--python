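"""Generator contracts: closed forms, determinism, and independent oracles."""

import numpy as np
import pytest
from scipy import optimize

from gqion.bindfit import wiseman_heats
from gqion.errors import ProtocolError
from gqion.synthgen import (FluxProtocol, NoiseSpec, gen_dose_response,
                            gen_flux_trace, gen_gating_trace, gen_itc,
                            gen_job_series, gen_melt_curve, gen_tail_iv,
                            gen_titration, solve_job_equilibrium)

QUIET = NoiseSpec(sigma=0.0, seed=0)


class TestFluxTraceGenerator:
    def test_zero_rate_stays_at_baseline_until_lysis(self):
        tr = gen_flux_trace(0.0, 0.8, noise=QUIET)
        pre_lysis = tr.times <= tr.t_lysis
        assert np.all(tr.signal[pre_lysis] == 0.0)
        assert np.all(tr.signal[tr.times > tr.t_lysis] == 1.0)

    def test_closed_form_one_relaxation_time(self):
        k = 0.05
        tr = gen_flux_trace(k, 1.0, noise=QUIET)
        assert tr.value_at(tr.t_base + 1.0 / k) == pytest.approx(1 - np.e ** -1,
                                                                 abs=1e-3)

    def test_invalid_protocol_ordering_rejected(self):
        with pytest.raises(ProtocolError):
            FluxProtocol(t_start=0, t_base=400, t_lysis=350, t_end=500)

    def test_raw_mode_applies_affine_transform(self):
        quiet = gen_flux_trace(0.06, 0.9, noise=QUIET)
        raw = gen_flux_trace(0.06, 0.9, noise=QUIET, baseline=100.0, scale=5.0)
        assert not raw.normalized
        np.testing.assert_allclose(raw.signal, 100.0 + 5.0 * quiet.signal)


class TestDoseResponseGenerator:
    def test_half_maximal_at_ec50(self):
        dr = gen_dose_response(19.0, 1.76, [19.0], QUIET)
        assert dr.activity[0] == pytest.approx(0.5)

    def test_hyperbolic_three_quarters_at_three_ec50(self):
        dr = gen_dose_response(10.0, 1.0, [30.0], QUIET)
        assert dr.activity[0] == pytest.approx(0.75)

    def test_noise_clipped_to_unit_interval(self):
        dr = gen_dose_response(5.0, 2.0, np.linspace(0, 100, 30),
                               NoiseSpec(0.2, seed=3))
        assert dr.activity.min() >= 0.0 and dr.activity.max() <= 1.0


class TestMeltCurveGenerator:
    temps = np.arange(25.0, 95.5, 0.5)

    def test_midpoint_of_baselines_at_tm(self):
        mc = gen_melt_curve(60.0, 3.0, self.temps, baselines=(0.2, 0.8),
                            noise=QUIET)
        assert np.interp(60.0, mc.temps, mc.signal) == pytest.approx(0.5)

    def test_high_temperature_asymptote(self):
        mc = gen_melt_curve(40.0, 2.0, self.temps, baselines=(0.0, 1.0),
                            noise=QUIET)
        assert mc.signal[-1] == pytest.approx(1.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        from gqion.errors import InsufficientDataError
        with pytest.raises(InsufficientDataError):
            gen_melt_curve(60.0, 3.0, [30, 40, 50, 60, 70], noise=QUIET)


class TestTitrationGenerator:
    def test_zero_titrant_gives_zero_signal(self):
        ts = gen_titration(3.2, 10.0, [0.0, 1.0, 2.0], noise=QUIET)
        assert ts.signal[0] == 0.0

    def test_saturation_plateau_at_large_excess(self):
        ts = gen_titration(0.5, 2.0, [1000.0], amplitude=7.0, noise=QUIET)
        assert ts.signal[0] == pytest.approx(7.0, rel=1e-2)


class TestJobGenerator:
    fractions = np.arange(0.05, 0.96, 0.05)

    def test_symmetric_1to1_peaks_at_half(self):
        js = gen_job_series(1, 1e7, 30.0, self.fractions, QUIET)
        assert js.mole_fractions[np.argmax(js.signal)] == pytest.approx(0.5)

    def test_3to1_peaks_at_three_quarters(self):
        js = gen_job_series(3, 1e6, 30.0, self.fractions, QUIET)
        assert js.mole_fractions[np.argmax(js.signal)] == pytest.approx(0.75)

    def test_signal_vanishes_at_pure_endpoints(self):
        js = gen_job_series(2, 1e5, 30.0, [0.0, 0.5, 1.0], QUIET)
        assert js.signal[0] == 0.0 and js.signal[-1] == 0.0
        assert np.all(js.signal >= 0.0)

    def test_solver_matches_brute_force_root_scan(self):
        # oracle: scan the mass-balance residual over a fine complex grid
        m, ka, ltot, qtot = 3, 2.0e4, 22.5, 7.5
        cmax = min(ltot / m, qtot)
        grid = np.linspace(0.0, cmax, 2_000_001)
        resid = ka * (ltot - m * grid) ** m * (qtot - grid) - grid
        idx = np.flatnonzero(np.diff(np.sign(resid)) != 0)[0]
        brute = grid[idx] - resid[idx] * (grid[idx + 1] - grid[idx]) / \
            (resid[idx + 1] - resid[idx])
        solved = solve_job_equilibrium(m, ka, ltot, qtot)
        assert solved == pytest.approx(brute, rel=1e-6)


class TestITCGenerator:
    def test_athermal_binding_gives_zero_heats(self):
        itc = gen_itc(3.0, 4.48, 0.0, 15.0, 450.0, noise=QUIET)
        np.testing.assert_array_equal(itc.heats, 0.0)

    def test_tight_binding_step_isotherm(self):
        # kd -> 0: constant molar heat before the equivalence point, ~0 after
        itc = gen_itc(2.0, 1e-9, -10.0, 50.0, 1000.0, n_inject=25,
                      noise=QUIET)
        before = itc.heats[itc.molar_ratios < 1.8]
        after = itc.heats[itc.molar_ratios > 2.2]
        np.testing.assert_allclose(before, -10.0, rtol=1e-4)
        np.testing.assert_allclose(after, 0.0, atol=1e-3)

    def test_heats_match_finite_difference_oracle(self):
        # oracle: independent root-solved equilibrium + finite differences
        n_sites, kd, dh = 3.0, 4.48, -8.0
        cell0, syr, v, v0, n = 15.0, 450.0, 10.0, 1400.0, 20
        f = v / v0
        q_cell, l_tot, bound_prev = cell0, 0.0, 0.0
        expected = []
        for _ in range(n):
            q_cell *= (1 - f)
            l_tot = l_tot * (1 - f) + syr * f
            sites = n_sites * q_cell

            def mass_balance(b, sites=sites, l_tot=l_tot):
                return (l_tot - b) * (sites - b) / kd - b

            bound = optimize.brentq(mass_balance, 0.0, min(sites, l_tot),
                                    xtol=1e-14)
            expected.append(dh * v0 * (bound - bound_prev * (1 - f)) / (syr * v))
            bound_prev = bound
        itc = gen_itc(n_sites, kd, dh, cell0, syr, n_inject=n, v_inject=v,
                      cell_vol=v0, noise=QUIET)
        np.testing.assert_allclose(itc.heats, expected, rtol=1e-8)


class TestGatingGenerator:
    def test_always_closed_trace_is_zero(self):
        tr = gen_gating_trace(1.6, 20.0, 0.0, 10.0, 500.0, 10.0, QUIET)
        np.testing.assert_array_equal(tr.current, 0.0)

    def test_open_level_is_ohmic_product(self):
        tr = gen_gating_trace(1.6, 20.0, 1.0, 10.0, 100.0, 10.0, QUIET)
        np.testing.assert_array_equal(tr.current, 32.0)

    def test_open_fraction_converges_to_p_open(self):
        # Monte-Carlo frequency oracle: binomial error with dwell-count n_eff
        p, tau, dur = 0.4, 5.0, 20000.0
        tr = gen_gating_trace(1.0, 20.0, p, tau, dur, 10.0,
                              NoiseSpec(0.0, seed=11))
        frac = np.mean(tr.current > 16.0)
        n_eff = dur / (tau / p)          # number of gating cycles
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(frac - p) < 3 * se


class TestTailIVGenerator:
    def test_current_vanishes_at_reversal(self):
        iv = gen_tail_iv(0.0, 1.4, [-50.0, 0.0, 50.0], QUIET)
        assert iv.currents[1] == 0.0

    def test_linear_evaluation(self):
        iv = gen_tail_iv(0.0, 1.4, [-50.0, 50.0], QUIET)
        assert iv.currents[1] == pytest.approx(70.0)


class TestDeterminism:
    """Identical seed and parameters give bit-identical outputs."""

    @pytest.mark.parametrize("make", [
        lambda s: gen_flux_trace(0.062, 0.9, noise=NoiseSpec(0.02, s)).signal,
        lambda s: gen_dose_response(19, 1.76, [0, 10, 30, 60],
                                    NoiseSpec(0.03, s)).activity,
        lambda s: gen_melt_curve(76, 3, np.arange(25, 96, 1.0),
                                 noise=NoiseSpec(0.02, s)).signal,
        lambda s: gen_titration(3.2, 10, np.linspace(0.5, 18, 12),
                                noise=NoiseSpec(0.02, s)).signal,
        lambda s: gen_job_series(3, 1e6, 30, np.arange(0.1, 0.91, 0.1),
                                 NoiseSpec(0.02, s)).signal,
        lambda s: gen_itc(3, 4.48, -8, 15, 450, noise=NoiseSpec(0.02, s)).heats,
        lambda s: gen_gating_trace(1.6, 20, 0.4, 10, 500, 10,
                                   NoiseSpec(0.05, s)).current,
        lambda s: gen_tail_iv(11, 1, np.arange(-90, 71, 10.0),
                              NoiseSpec(0.02, s)).currents,
    ], ids=["flux", "dose", "melt", "titration", "job", "itc", "gating", "iv"])
    def test_same_seed_bit_identical_different_seed_not(self, make):
        a, b, c = make(7), make(7), make(8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_replicates_independent_of_generation_order(self):
        spec = NoiseSpec(0.02, seed=5)
        r2_first = gen_flux_trace(0.06, 0.9, noise=spec, replicate=2).signal
        _ = gen_flux_trace(0.06, 0.9, noise=spec, replicate=0)
        r2_again = gen_flux_trace(0.06, 0.9, noise=spec, replicate=2).signal
        np.testing.assert_array_equal(r2_first, r2_again)
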