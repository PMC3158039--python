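"""Equilibrium analysis: jackknife averages, two-state fits, specific
heat, free-energy surfaces, reweighting, and barrier extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from pdzmc.sampling import Trajectory
from pdzmc.synthetic import make_two_state_samples
from pdzmc.thermo import (
    BarrierResult,
    BindingCurve,
    barrier_height,
    binding_curve,
    cv_from_samples,
    fit_two_state,
    free_energy_surface,
    p_bound_curve,
    reweight_single_histogram,
    reweighted_mean,
    specific_heat,
    thermal_average,
    two_state_model,
)


def fake_traj(values, T=1.0, extra=None):
    """Wrap raw observable samples in a minimal Trajectory."""
    n = len(values)
    df = pd.DataFrame({"step": np.arange(n), "k": 0, "T": T, "E_total": values})
    if extra:
        for k, v in extra.items():
            df[k] = v
    meta = {"temperatures": [T], "attempted": [0] * 8, "accepted": [0] * 8}
    return Trajectory(
        df=df, meta=meta, pep_coords=np.empty((0, 0, 3)),
        min_energy=float(np.min(values)), min_coords=np.empty((0, 3)),
    )


class TestThermalAverage:
    def test_constant_observable(self):
        traj = fake_traj(np.full(200, 3.5))
        m, e = thermal_average(traj, "E_total", equilibration=0.0)
        assert m == pytest.approx(3.5)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_jackknife_matches_sem_for_iid_gaussian(self):
        """Over 100 repetitions, the jackknife error of the mean of
        i.i.d. Gaussians tracks sigma/sqrt(n) within 20%."""
        rng = np.random.default_rng(17)
        n = 2000
        ratios = []
        for _ in range(100):
            x = rng.normal(size=n)
            _, err = thermal_average(fake_traj(x), "E_total", equilibration=0.0)
            ratios.append(err / (1.0 / math.sqrt(n)))
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_two_runs_with_different_means(self):
        a, b = fake_traj(np.zeros(50)), fake_traj(np.ones(50))
        m, e = thermal_average([a, b], "E_total", equilibration=0.0)
        assert m == pytest.approx(0.5)
        assert e > 0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            thermal_average(fake_traj(np.ones(1)), "E_total", equilibration=0.0)


class TestTwoStateFit:
    def test_noiseless_recovery(self):
        curve = make_two_state_samples(
            0.0, 1.0, dE=50.0, Tm=0.5, temperatures=np.linspace(0.3, 0.9, 10),
            noise=0.0,
        )
        fit = fit_two_state(curve)
        assert fit.converged
        assert fit.X_U == pytest.approx(0.0, abs=1e-6)
        assert fit.X_B == pytest.approx(1.0, abs=1e-6)
        assert fit.dE == pytest.approx(50.0, rel=1e-6)
        assert fit.Tm == pytest.approx(0.5, rel=1e-6)

    def test_midpoint_value(self):
        assert two_state_model(0.5, 2.0, 8.0, 30.0, 0.5) == pytest.approx(5.0)
        fitted = fit_two_state(
            make_two_state_samples(2.0, 8.0, 30.0, 0.5, np.linspace(0.3, 0.9, 8))
        )
        assert fitted.predict(np.array([fitted.Tm]))[0] == pytest.approx(
            (fitted.X_U + fitted.X_B) / 2, rel=1e-9
        )

    def test_recovery_study_two_percent_noise(self):
        """100 replicates, 8 temperatures, 2% per-sample noise with 100
        samples per temperature: median relative errors below 1% (Tm)
        and 5% (dE).  The truth (dE=15, Tm=0.8) puts the transition
        width on the scale the 8-point ladder resolves, as for the toy
        binding curves."""
        from pdzmc.sampling import STSchedule

        temps = STSchedule.geometric(0.4, 1.6, 8).temperatures
        tm_err, de_err = [], []
        for rep in range(100):
            curve = make_two_state_samples(
                0.0, 1.0, 15.0, 0.8, temps, n_per_T=100, noise=0.02, seed=rep
            )
            fit = fit_two_state(curve)
            assert fit.converged
            tm_err.append(abs(fit.Tm - 0.8) / 0.8)
            de_err.append(abs(fit.dE - 15.0) / 15.0)
        assert np.median(tm_err) < 0.01
        assert np.median(de_err) < 0.05

    def test_flat_curve_flagged(self):
        curve = BindingCurve(np.linspace(0.3, 0.9, 6), np.ones(6), np.zeros(6))
        fit = fit_two_state(curve)
        assert not fit.converged
        assert any("unidentifiable" in f for f in fit.flags)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_two_state(BindingCurve(np.array([0.3, 0.5, 0.7]), np.zeros(3), np.zeros(3)))


class TestSpecificHeat:
    def test_two_level_schottky_closed_form(self):
        """The fluctuation formula under exact two-level weights equals
        the closed-form Schottky specific heat to 1e-9."""
        eps = 2.0
        energies = np.array([0.0, eps])
        for T in np.linspace(0.2, 3.0, 15):
            w = np.exp(-energies / T)
            got = cv_from_samples(energies, T, n_res=1, weights=w)
            x = eps / T
            expect = x * x * math.exp(x) / (1.0 + math.exp(x)) ** 2
            assert got == pytest.approx(expect, abs=1e-9)

    def test_constant_energy_zero(self):
        traj = fake_traj(np.full(400, -3.0))
        cv = specific_heat([traj, fake_traj(np.full(400, -3.0))], n_res=5)
        assert np.allclose(cv.means, 0.0)

    def test_cv_peak_near_tm_for_constructed_two_state(self):
        """For an exactly constructed two-state system (ground state
        vs degenerate excited manifold with Tm = dE/dS), the Cv peak
        lies within one grid step of Tm."""
        dE, Tm = 50.0, 0.5
        dS = dE / Tm
        # levels: E=0 (bound, g=1) and E=dE (unbound, g=e^dS)
        energies = np.array([0.0, dE])
        log_g = np.array([0.0, dS])
        grid = np.arange(0.40, 0.60, 0.01)
        cvs = []
        for T in grid:
            logw = log_g - energies / T
            w = np.exp(logw - logw.max())
            cvs.append(cv_from_samples(energies, T, n_res=1, weights=w))
        t_peak = grid[int(np.argmax(cvs))]
        assert abs(t_peak - Tm) <= 0.01 + 1e-12


class TestPBound:
    def test_all_bound(self):
        traj = fake_traj(np.zeros(100), extra={"rmsd": np.full(100, 1.0)})
        pb = p_bound_curve([traj, traj], equilibration=0.0)
        assert np.allclose(pb.means, 1.0)

    def test_cutoff_monotonicity(self, rng):
        rmsd = rng.uniform(0, 15, 500)
        traj = fake_traj(np.zeros(500), extra={"rmsd": rmsd})
        p6 = p_bound_curve([traj, traj], r_cut=6.0, equilibration=0.0).means
        p9 = p_bound_curve([traj, traj], r_cut=9.0, equilibration=0.0).means
        assert (p9 >= p6).all()


class TestFreeEnergySurface:
    def test_uniform_two_bins_zero_delta(self, rng):
        x = np.concatenate([np.full(5000, 0.1), np.full(5000, 0.4)])
        df = pd.DataFrame({"E_total": rng.normal(size=10000), "dcm": x})
        fes = free_energy_surface(df, T=1.0, x="dcm")
        occupied = fes.profile_x[np.isfinite(fes.profile_x)]
        assert occupied.max() - occupied.min() == pytest.approx(0.0, abs=1e-12)

    def test_log_ratio_of_bin_probabilities(self, rng):
        """p = (0.8, 0.2) at T=1 gives delta F = ln 4 within binomial error."""
        n = 40000
        x = np.where(rng.random(n) < 0.8, 0.1, 0.4)
        df = pd.DataFrame({"E_total": rng.normal(size=n), "dcm": x})
        fes = free_energy_surface(df, T=1.0, x="dcm")
        occ = fes.profile_x[np.isfinite(fes.profile_x)]
        delta = occ.max() - occ.min()
        sem = math.sqrt(1 / (0.2 * n) + 1 / (0.8 * n))  # error of the log-ratio
        assert abs(delta - math.log(4.0)) < 3 * sem

    def test_double_well_sampler_recovery(self, rng):
        """Samples from a known double-well Boltzmann density recover
        the constructed inter-minimum free-energy difference."""
        T = 1.0
        xgrid = np.linspace(-2, 2, 161)
        f = 2.0 * (xgrid**2 - 1.0) ** 2 + 0.5 * xgrid  # asymmetric double well
        p = np.exp(-f / T)
        p /= p.sum()
        idx = rng.choice(len(xgrid), size=200000, p=p)
        x = xgrid[idx]
        df = pd.DataFrame({"E_total": np.zeros(len(x)), "dcm": x})
        fes = free_energy_surface(df, T=T, x="dcm", x_bin_width=0.05)
        prof = fes.profile_x
        c = fes.x_centers
        left = prof[(c > -1.3) & (c < -0.7)].min()
        right = prof[(c > 0.7) & (c < 1.3)].min()
        # construction: wells at ~ -1 and ~ +1 differ by ~ the tilt 1.0
        assert right - left == pytest.approx(1.0, abs=0.12)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            free_energy_surface(pd.DataFrame({"E_total": [], "dcm": []}), T=1.0)


class TestReweighting:
    def test_identity_at_same_temperature(self, rng):
        df = pd.DataFrame({"E_total": rng.normal(size=1000)})
        w, ess, flags = reweight_single_histogram(df, 1.0, 1.0)
        assert np.allclose(w, 1.0 / 1000)
        assert ess == pytest.approx(1000)
        assert not flags

    def test_gaussian_closed_form_shift(self, rng):
        """For Gaussian energies, reweighting shifts the mean by
        -sigma^2 * d(1/T)."""
        mu, sigma = -30.0, 4.0
        e = rng.normal(mu, sigma, size=400000)
        df = pd.DataFrame({"E_total": e})
        T0, T1 = 1.0, 1.05
        got = reweighted_mean(df, "E_total", T0, T1)
        expect = mu - sigma**2 * (1.0 / T1 - 1.0 / T0)
        assert got == pytest.approx(expect, abs=0.1)

    def test_low_ess_flagged(self, rng):
        df = pd.DataFrame({"E_total": rng.normal(0, 30, size=500)})
        _, _, flags = reweight_single_histogram(df, 1.0, 0.5)
        assert flags

    def test_enumerable_cross_check(self, enumerable):
        """Reweighting samples drawn at T to 1.1 T reproduces the exact
        enumerated mean energy."""
        from pdzmc.energy import EnergyParams
        from pdzmc.sampling import run_fixed_T

        es = enumerable
        T0 = 1.0
        traj = run_fixed_T(
            es.system, EnergyParams(), T0, 150000, seed=31,
            move_set=es.move_set, mobility=es.mobility, record_every=10,
            store_snapshots=False,
        )
        df = traj.df.iloc[200:]
        got = reweighted_mean(df, "E_total", T0, 1.1 * T0)
        exact = es.exact_mean_energy(1.1 * T0)
        # block jackknife error of the reweighted estimate
        blocks = np.array_split(df, 20)
        ests = np.array([reweighted_mean(b, "E_total", T0, 1.1 * T0) for b in blocks])
        err = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(got - exact) < max(3 * err, 0.02)


class TestBarrier:
    @staticmethod
    def double_well(depth=3.0, n=201):
        x = np.linspace(-2.0, 2.0, n)
        return x, depth * (x**2 - 1.0) ** 2

    def test_exact_double_well(self):
        x, f = self.double_well(depth=3.0)
        res = barrier_height(x, f, bound_region=(-1.5, -0.5))
        assert res.has_barrier
        assert res.delta_f == pytest.approx(3.0, abs=1e-12)
        assert res.ts_x == pytest.approx(0.0, abs=1e-9)
        assert res.bound_x == pytest.approx(-1.0, abs=1e-9)

    def test_monotone_profile_no_barrier(self):
        x = np.linspace(0, 10, 100)
        res = barrier_height(x, 0.5 * x, bound_region=(0.0, 2.0))
        assert not res.has_barrier
        assert math.isnan(res.delta_f)

    def test_gauge_invariance(self):
        x, f = self.double_well(depth=2.0)
        a = barrier_height(x, f, (-1.5, -0.5))
        b = barrier_height(x, f + 123.4, (-1.5, -0.5))
        assert a.delta_f == pytest.approx(b.delta_f, abs=1e-12)

    def test_infinite_bins_ignored(self):
        x, f = self.double_well(depth=2.0)
        f2 = f.copy()
        f2[::7] = np.inf  # unoccupied bins
        res = barrier_height(x, f2, (-1.5, -0.5))
        assert res.has_barrier
        assert res.delta_f == pytest.approx(2.0, rel=0.05)
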