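"""Brownian-dynamics surrogate: dynamics, currents, densities, PMFs."""

import numpy as np
import pytest

from gqion.errors import ModelError, StepSizeError, TrajectoryError
from gqion.permbd import (KT_EMV_298, PA_PER_E_NS, ChannelModel,
                          IonTrajectory, SpeciesSpec, density_profile,
                          gaussian_barrier_pmf, iv_scan, pmf_boltzmann,
                          run_bd, total_intensity_current)

L = 10.0
FLAT = np.zeros(101)


def flat_model(n_ions=20, d=2.0, q=1.0):
    return ChannelModel([SpeciesSpec("K+", q, d, FLAT, n_ions)], L)


def drift_current_pa(n, q, d, v, l=L):
    """Closed-form mean current of independent drifting ions, pA."""
    return n * q * q * d * v / (KT_EMV_298 * l * l) * PA_PER_E_NS


class TestRunBD:
    def test_frozen_dynamics_without_diffusion(self):
        traj = run_bd(flat_model(d=0.0), 50.0, 1000, 0.02, seed=1)
        np.testing.assert_array_equal(traj.z_wrapped[0], traj.z_wrapped[-1])

    def test_einstein_relation_msd(self):
        # mean squared displacement per lag equals 2 D tau (flat PMF, V=0);
        # disjoint frame-to-frame increments are i.i.d., giving tight stats
        d = 2.0
        traj = run_bd(flat_model(n_ions=50, d=d), 0.0, 20000, 0.02, seed=2)
        dz = np.diff(traj.z_unwrapped, axis=0).ravel()
        tau = np.diff(traj.times)[0]
        msd_rate = float(np.mean(dz ** 2)) / tau
        n = dz.size
        se = np.sqrt(2.0 / n) * 2 * d
        assert abs(msd_rate - 2 * d) < 3 * se

    def test_drift_velocity_closed_form(self):
        q, d, v = 1.0, 2.0, 100.0
        traj = run_bd(flat_model(n_ions=50, d=d, q=q), v, 20000, 0.02, seed=3)
        t_tot = traj.times[-1]
        vel = (traj.z_unwrapped[-1] - traj.z_unwrapped[0]).mean() / t_tot
        expected = q * d * v / (KT_EMV_298 * L)
        se = (traj.z_unwrapped[-1] - traj.z_unwrapped[0]).std() / t_tot \
            / np.sqrt(50)
        assert abs(vel - expected) < 3 * se

    def test_seeded_reproducibility(self):
        a = run_bd(flat_model(), 50.0, 500, 0.02, seed=9)
        b = run_bd(flat_model(), 50.0, 500, 0.02, seed=9)
        np.testing.assert_array_equal(a.z_unwrapped, b.z_unwrapped)

    def test_step_size_guard(self):
        steep = gaussian_barrier_pmf(L, 50 * KT_EMV_298, 0.5)
        model = ChannelModel([SpeciesSpec("K+", 1, 2.0, steep, 5)], L)
        with pytest.raises(StepSizeError):
            run_bd(model, 0.0, 100, 1.0, seed=1)

    def test_non_periodic_pmf_rejected(self):
        w = np.linspace(0.0, 5.0, 101)     # tilted, W(0) != W(L)
        with pytest.raises(ModelError):
            SpeciesSpec("K+", 1, 2.0, w, 5)

    def test_wrapped_unwrapped_consistency(self):
        traj = run_bd(flat_model(), 80.0, 5000, 0.02, seed=4)
        winding = (traj.z_unwrapped - traj.z_wrapped) / L
        np.testing.assert_allclose(winding, np.round(winding), atol=1e-9)


class TestTotalIntensityCurrent:
    def test_single_crossing_bookkeeping(self):
        # one +1 ion crossing the full box once in total time t -> I = e/t
        times = np.linspace(0.0, 10.0, 11)
        zu = np.linspace(0.0, L, 11)[:, None]
        traj = IonTrajectory(times=times, z_wrapped=np.mod(zu, L),
                             z_unwrapped=zu, species=np.array(["K+"]),
                             charges=np.array([1.0]), v_applied=0.0, l_z=L,
                             dt=1.0)
        res = total_intensity_current(traj, equil_fraction=0.0)
        assert res.mean_pa == pytest.approx(PA_PER_E_NS / 10.0)
        assert res.cumulative_charge_e[-1] == pytest.approx(1.0)

    def test_equilibrium_current_within_3se_of_zero(self):
        traj = run_bd(flat_model(), 0.0, 30000, 0.02, seed=5)
        res = total_intensity_current(traj)
        assert abs(res.mean_pa) < 3 * res.se_pa

    def test_biased_flat_pmf_matches_drift_closed_form(self):
        v = 100.0
        traj = run_bd(flat_model(n_ions=30), v, 60000, 0.02, seed=6)
        res = total_intensity_current(traj)
        assert res.mean_pa == pytest.approx(drift_current_pa(30, 1, 2.0, v),
                                            abs=3 * res.se_pa)

    def test_species_currents_sum_exactly_to_total(self):
        w = gaussian_barrier_pmf(L, 2 * KT_EMV_298, 1.5)
        model = ChannelModel([
            SpeciesSpec("K+", 1.0, 2.0, w, 12),
            SpeciesSpec("Cl-", -1.0, 2.0, w * 3, 12),
        ], L)
        traj = run_bd(model, 75.0, 20000, 0.01, seed=7)
        res = total_intensity_current(traj)
        summed = sum(res.species_current_pa.values())
        np.testing.assert_allclose(summed, res.current_pa, atol=1e-10)

    def test_cumulative_charge_is_time_integral_of_current(self):
        traj = run_bd(flat_model(), 50.0, 5000, 0.02, seed=8)
        res = total_intensity_current(traj)
        dt = np.diff(traj.times)[0]
        np.testing.assert_allclose(
            res.cumulative_charge_e,
            np.cumsum(res.current_pa * dt) / PA_PER_E_NS, rtol=1e-12)

    def test_cumulative_charge_grows_linearly_under_bias(self):
        traj = run_bd(flat_model(n_ions=30), 100.0, 60000, 0.02, seed=10)
        res = total_intensity_current(traj)
        start = int(0.25 * res.t_mid.size)
        t, q = res.t_mid[start:], res.cumulative_charge_e[start:]
        pred = np.polyval(np.polyfit(t, q, 1), t)
        r2 = 1 - np.sum((q - pred) ** 2) / np.sum((q - q.mean()) ** 2)
        assert r2 > 0.99

    def test_inconsistent_frame_gaps_rejected(self):
        times = np.array([0.0, 1.0, 3.0])
        z = np.zeros((3, 1))
        traj = IonTrajectory(times=times, z_wrapped=z, z_unwrapped=z,
                             species=np.array(["K+"]),
                             charges=np.array([1.0]), v_applied=0.0, l_z=L,
                             dt=1.0)
        with pytest.raises(TrajectoryError):
            total_intensity_current(traj)


class TestIVScan:
    VOLTS = [-100.0, -50.0, 50.0, 100.0]

    def test_flat_pmf_conductance_matches_closed_form(self):
        scan = iv_scan(flat_model(n_ions=30), self.VOLTS, 40000, 0.02, seed=11)
        g_expected = drift_current_pa(30, 1, 2.0, 1.0)  # pA/mV = nS
        g_se = np.mean(scan.se_pa) / np.std(self.VOLTS)
        assert scan.g_ns == pytest.approx(g_expected, abs=3 * g_se)
        assert scan.linear

    def test_current_antisymmetric_for_symmetric_pmf(self):
        w = gaussian_barrier_pmf(L, 1.5 * KT_EMV_298, 1.5)
        model = ChannelModel([SpeciesSpec("K+", 1, 2.0, w, 30)], L)
        scan = iv_scan(model, [-100.0, 100.0], 40000, 0.02, seed=12)
        i_neg, i_pos = scan.iv.currents
        tol = 3 * np.hypot(*scan.se_pa)
        assert abs(i_pos + i_neg) < tol

    def test_high_barrier_species_carries_no_current(self):
        low = gaussian_barrier_pmf(L, 1.0 * KT_EMV_298, 1.5)
        model = ChannelModel([
            SpeciesSpec("K+", 1.0, 2.0, low, 15),
            SpeciesSpec("Cl-", -1.0, 2.0, low * 10.0, 15),
        ], L)
        traj = run_bd(model, 100.0, 120000, 0.01, seed=13)
        res = total_intensity_current(traj)
        i_k = res.species_mean_pa["K+"][0]
        i_cl = res.species_mean_pa["Cl-"][0]
        assert abs(i_cl) < 0.1 * abs(i_k)

    def test_requires_biases_of_both_signs(self):
        with pytest.raises(ValueError):
            iv_scan(flat_model(), [10.0, 20.0], 100, 0.02, seed=1)


class TestDensityAndPMF:
    def test_flat_pmf_density_uniform(self):
        traj = run_bd(flat_model(n_ions=40), 0.0, 40000, 0.02, seed=14)
        centers, prof = density_profile(traj, n_bins=20)
        rho = prof["K+"]
        mean = rho.mean()
        assert np.all(np.abs(rho - mean) < 0.15 * mean)

    def test_density_integrates_to_ion_count(self):
        traj = run_bd(flat_model(n_ions=17), 0.0, 2000, 0.02, seed=15)
        centers, prof = density_profile(traj, n_bins=25)
        width = L / 25
        assert prof["K+"].sum() * width == pytest.approx(17.0)

    def test_harmonic_well_density_is_gaussian(self):
        # Boltzmann: rho ~ exp(-W/kT); W = k/2 (z-z0)^2 -> Gaussian density
        kspring = 2.0 * KT_EMV_298   # e*mV per nm^2
        z = np.linspace(0, L, 101)
        w = 0.5 * kspring * (z - L / 2) ** 2
        w[0] = w[-1] = w[[0, -1]].min()   # identical ends (already symmetric)
        model = ChannelModel([SpeciesSpec("K+", 1, 2.0, w, 40)], L)
        traj = run_bd(model, 0.0, 150000, 0.004, seed=16)
        centers, prof = density_profile(traj, n_bins=40,
                                        equil_fraction=0.25)
        rho = prof["K+"]
        sigma_pred = np.sqrt(KT_EMV_298 / kspring)
        mu = np.sum(centers * rho) / rho.sum()
        var = np.sum((centers - mu) ** 2 * rho) / rho.sum()
        assert mu == pytest.approx(L / 2, abs=0.2)
        assert np.sqrt(var) == pytest.approx(sigma_pred, rel=0.15)

    def test_uniform_density_inverts_to_zero_pmf(self):
        rho = np.full(30, 4.0)
        w, good = pmf_boltzmann(rho, flat_model())
        np.testing.assert_allclose(w, 0.0, atol=1e-12)
        assert good.all()

    def test_round_trip_recovers_barrier_within_02_kt(self):
        w_in = gaussian_barrier_pmf(L, 2.0 * KT_EMV_298, 1.5)
        model = ChannelModel([SpeciesSpec("K+", 1, 2.0, w_in, 20)], L)
        traj = run_bd(model, 0.0, 200000, 0.02, seed=17)
        centers, prof = density_profile(traj, n_bins=50, equil_fraction=0.25)
        w_est, good = pmf_boltzmann(prof["K+"], model)
        w_true = np.interp(centers, np.linspace(0, L, w_in.size), w_in)
        rmse = np.sqrt(np.nanmean((w_est[good] - w_true[good]) ** 2))
        assert rmse < 0.2 * KT_EMV_298

    def test_two_species_barrier_ratio_recovered(self):
        w1 = gaussian_barrier_pmf(L, 1.0 * KT_EMV_298, 1.8)
        model = ChannelModel([
            SpeciesSpec("K+", 1, 2.0, w1, 25),
            SpeciesSpec("Cl-", -1, 2.0, w1 * 4.0, 25),
        ], L)
        traj = run_bd(model, 0.0, 150000, 0.02, seed=18)
        centers, prof = density_profile(traj, n_bins=40, equil_fraction=0.25)
        wk, _ = pmf_boltzmann(prof["K+"], model)
        wcl, _ = pmf_boltzmann(prof["Cl-"], model)
        ratio = np.nanmax(wcl) / np.nanmax(wk)
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_empty_bulk_reference_rejected(self):
        rho = np.zeros(30)
        rho[14:16] = 5.0
        with pytest.raises(ModelError):
            pmf_boltzmann(rho, flat_model())


class TestEquilibriumZeroCurrentProperty:
    def test_zero_bias_current_within_3se_over_replicates(self):
        # any PMF: 20 seeded replicates, mean current consistent with zero
        w = gaussian_barrier_pmf(L, 1.0 * KT_EMV_298, 2.0)
        model = ChannelModel([SpeciesSpec("K+", 1, 2.0, w, 10)], L)
        means = []
        for rep in range(20):
            traj = run_bd(model, 0.0, 8000, 0.02, seed=1000 + rep)
            means.append(total_intensity_current(traj).mean_pa)
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 3 * se
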