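"""Langevin engine, SMD work accumulation, ABMD ratchet, Debye–Hückel CV
and well-tempered metadynamics hill bookkeeping."""

import numpy as np
import pytest

from pathwork.thermo import ThermoContext
from pathwork.toy_dynamics import (
    ABMDResult,
    DebyeHuckelParams,
    DoubleWell1D,
    DoubleWell2D,
    DynamicsError,
    Flat,
    Harmonic,
    HillsParams,
    SMDSchedule,
    ToySystem,
    abmd_run,
    coordinate_cv,
    debye_huckel_energy,
    langevin_run,
    linear_toy_path,
    make_potential,
    smd_run,
    wtmetad_run,
)

T300 = ThermoContext(300.0)
TCOLD = ThermoContext(1e-9)


class TestLangevin:
    def test_cold_start_at_minimum_is_stationary(self):
        sys1 = ToySystem(Harmonic(k=2.0), dim=1, thermo=TCOLD)
        traj = langevin_run(sys1, duration=2.0, dt=0.002, x0=0.0, seed=1)
        xs = traj.coords_array()[:, 0, 0]
        # thermal noise amplitude ~ √(RT/k) ≈ 2e-5 Å at T = 1e-9 K
        np.testing.assert_allclose(xs, 0.0, atol=1e-4)

    def test_equipartition_harmonic(self):
        k_h = 1.0
        sys1 = ToySystem(Harmonic(k=k_h), dim=1, mass=12.0, friction=5.0,
                         thermo=T300)
        traj = langevin_run(sys1, duration=600.0, dt=0.004, x0=0.0,
                            stride=500, seed=7)  # samples every 2 ps
        xs = traj.coords_array()[5:, 0, 0]  # discard brief equilibration
        x2 = xs**2
        se = x2.std(ddof=1) / np.sqrt(len(x2))
        assert x2.mean() == pytest.approx(T300.RT / k_h, abs=3 * se)

    def test_determinism(self):
        sys1 = ToySystem(DoubleWell1D(), dim=1, thermo=T300)
        t1 = langevin_run(sys1, duration=5.0, dt=0.002, x0=1.0, seed=3)
        t2 = langevin_run(sys1, duration=5.0, dt=0.002, x0=1.0, seed=3)
        np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())

    def test_divergence_is_reported_with_step(self):
        # unstable dt for a stiff harmonic well
        sys1 = ToySystem(Harmonic(k=5000.0), dim=1, mass=1.0, thermo=T300)
        with pytest.raises(DynamicsError, match="step"):
            langevin_run(sys1, duration=50.0, dt=0.1, x0=1.0, seed=0)

    def test_2d_double_well_runs(self):
        sys2 = ToySystem(DoubleWell2D(), dim=2, thermo=T300)
        traj = langevin_run(sys2, duration=5.0, dt=0.002, x0=[1.5, 0.0], seed=5)
        assert traj.coords_array().shape[2] == 3

    def test_make_potential_registry(self):
        p = make_potential("double_well", height=1.0, half_width=2.0)
        assert isinstance(p, DoubleWell1D)
        with pytest.raises(ValueError, match="unknown potential"):
            make_potential("lennard_jones")


class TestSMD:
    def test_frozen_particle_harmonic_work(self):
        """Immobile particle, restraint moved by Δ: W = kΔ²/2 exactly."""
        path = linear_toy_path(-2.5, 2.5, 21)
        frozen = ToySystem(Flat(1), dim=1, mass=1e12, friction=10.0, thermo=TCOLD)
        sched = SMDSchedule(k=10.0, s_start=0.3, s_end=0.8, duration=5.0)
        x0 = -2.5 + 0.3 * 5.0  # particle exactly at the s=0.3 node
        _, trace = smd_run(frozen, path, sched, dt=0.002, x0=x0, seed=2)
        assert trace.total_work == pytest.approx(10.0 * 0.5**2 / 2.0, rel=1e-6)

    def test_zero_pull_zero_work(self):
        path = linear_toy_path(-2.5, 2.5, 21)
        sys1 = ToySystem(DoubleWell1D(), dim=1, thermo=T300)
        sched = SMDSchedule(k=10.0, s_start=0.5, s_end=0.5, duration=2.0)
        _, trace = smd_run(sys1, path, sched, dt=0.002, seed=4)
        assert trace.total_work == 0.0

    def test_quasistatic_harmonic_second_law(self):
        """Slow pulls on a harmonic well: ⟨W⟩ ≈ ΔA and ⟨W_diss⟩ ≥ 0.

        The reference is the restrained free energy difference
        A(ŝ=1) − A(ŝ=0) by direct quadrature over the particle coordinate.
        """
        k_h, k_s = 2.0, 200.0
        sys1 = ToySystem(Harmonic(k=k_h), dim=1, mass=12.0, friction=5.0,
                         thermo=T300)
        path = linear_toy_path(-1.0, 1.0, 11)
        lam = path.lambda_
        xg = np.linspace(-2.5, 2.5, 4001)
        W = np.linspace(-1.0, 1.0, 11)
        a = np.exp(-lam * (xg[:, None] - W[None, :]) ** 2)
        sg = ((a * np.arange(1, 12)).sum(1) / a.sum(1) - 1.0) / 10.0
        V = 0.5 * k_h * xg**2

        def A(shat):
            u = np.exp(-T300.beta * (V + 0.5 * k_s * (sg - shat) ** 2))
            return -T300.RT * np.log(np.trapezoid(u, xg))

        dA = A(1.0) - A(0.0)
        sched = SMDSchedule(k=k_s, s_start=0.0, s_end=1.0, duration=8.0)
        works = []
        for i in range(30):
            _, tr = smd_run(sys1, path, sched, dt=0.002, x0=-1.0, seed=100 + i)
            works.append(tr.total_work)
        works = np.array(works)
        se = works.std(ddof=1) / np.sqrt(len(works))
        assert works.mean() == pytest.approx(dA, abs=3 * se + 0.05)
        assert works.mean() - dA >= -3 * se  # dissipated work non-negative

    def test_work_trace_invariants(self):
        path = linear_toy_path(-1.5, 1.5, 11)
        sys1 = ToySystem(DoubleWell1D(), dim=1, thermo=T300)
        sched = SMDSchedule(k=100.0, s_start=0.0, s_end=1.0, duration=4.0)
        _, tr = smd_run(sys1, path, sched, dt=0.002, seed=9)
        assert tr.w_accum[0] == 0.0
        assert len(tr.times) == len(tr.s_hat) == len(tr.s_inst) == len(tr.w_accum)
        # schedule is linear in time at constant velocity
        np.testing.assert_allclose(np.diff(tr.s_hat), np.diff(tr.s_hat)[0])


class TestABMD:
    @staticmethod
    def _dw_system():
        return ToySystem(DoubleWell1D(height=2.5, half_width=1.5, tilt=-1.0),
                         dim=1, mass=12.0, friction=5.0, thermo=T300)

    def test_start_at_target_no_bias(self):
        res = abmd_run(self._dw_system(), coordinate_cv(0, 1), target=-1.5,
                       k_abmd=20.0, duration=2.0, dt=0.002, x0=-1.5, seed=3)
        np.testing.assert_allclose(res.bias_energy, 0.0)
        assert res.reached_target

    def test_ratchet_monotone_toward_target(self):
        res = abmd_run(self._dw_system(), coordinate_cv(0, 1), target=1.5,
                       k_abmd=20.0, duration=20.0, dt=0.002, x0=-1.5, seed=5)
        assert isinstance(res, ABMDResult)
        assert np.all(np.diff(res.rho) >= 0)
        assert res.rho[-1] <= 1.5 + 1e-12

    def test_bias_zero_at_best_value(self):
        res = abmd_run(self._dw_system(), coordinate_cv(0, 1), target=1.5,
                       k_abmd=20.0, duration=10.0, dt=0.002, x0=-1.5, seed=6)
        at_best = res.cv_values >= res.rho - 1e-12
        assert np.all(res.bias_energy[at_best] == 0.0)

    def test_barrier_crossing_reliability(self):
        """Ratchet escape from the shallow to the deep basin in ≥ 9/10 runs."""
        hits = 0
        for seed in range(10):
            res = abmd_run(self._dw_system(), coordinate_cv(0, 1), target=1.5,
                           k_abmd=20.0, duration=100.0, dt=0.002, x0=-1.5,
                           seed=seed, target_tol=0.05)
            hits += res.reached_target
        assert hits >= 9


class TestDebyeHuckel:
    def test_coulomb_closed_form(self):
        params = DebyeHuckelParams(kappa=0.0, eps_r=1.0,
                                   charges_A=(1.0,), charges_B=(1.0,))
        e = debye_huckel_energy([[0.0, 0.0, 0.0]], [[3.320637, 0.0, 0.0]], params)
        assert e == pytest.approx(100.0, rel=1e-6)

    def test_zero_charges(self):
        params = DebyeHuckelParams(charges_A=(0.0,), charges_B=(0.0, 0.0))
        e = debye_huckel_energy([[0.0, 0, 0]], [[1.0, 0, 0], [2.0, 0, 0]], params)
        assert e == 0.0

    def test_strong_screening_limit(self):
        params = DebyeHuckelParams(kappa=1e3, charges_A=(1.0,), charges_B=(1.0,))
        e = debye_huckel_energy([[0.0, 0, 0]], [[2.0, 0, 0]], params)
        assert abs(e) < 1e-300

    def test_coincident_atoms_rejected(self):
        params = DebyeHuckelParams()
        with pytest.raises(ValueError, match="r = 0"):
            debye_huckel_energy([[1.0, 0, 0]], [[1.0, 0, 0]], params)


class TestWTMetaD:
    def test_hill_height_decay_closed_form(self):
        """First hill h₀; subsequent heights follow the WT decay rule.

        With h₀ = (γ−1)·RT·ln2 and an immobile particle the second hill is
        deposited where V_bias = h₀, hence its height is exactly h₀/2.
        """
        gamma = 5.0
        h0 = (gamma - 1.0) * T300.RT * np.log(2.0)
        path = linear_toy_path(-1.0, 1.0, 5)
        # huge mass keeps the particle immobile at finite temperature
        frozen = ToySystem(Flat(1), dim=1, mass=1e14, friction=10.0, thermo=T300)
        hp = HillsParams(height=h0, sigma_s=0.1, sigma_z=1.0, stride_steps=10,
                         bias_factor=gamma)
        res = wtmetad_run(frozen, path, hp, duration=0.06, dt=0.002,
                          x0=0.0, seed=1)
        h = res.hills.heights
        assert h[0] == pytest.approx(h0, rel=1e-9)
        assert h[1] == pytest.approx(h0 / 2.0, rel=1e-6)
        assert np.all(np.diff(h) < 0)
        assert np.all(h <= h0 + 1e-12)

    def test_bias_is_sum_of_gaussians(self):
        path = linear_toy_path(-1.5, 1.5, 11)
        sys1 = ToySystem(DoubleWell1D(), dim=1, thermo=T300)
        hp = HillsParams(height=0.3, sigma_s=0.05, sigma_z=1.0, stride_steps=100,
                         bias_factor=5.0)
        res = wtmetad_run(sys1, path, hp, duration=5.0, dt=0.002, x0=-1.5, seed=2)
        hills = res.hills
        s0, z0 = hills.centers_s[0], hills.centers_z[0]
        expected = sum(
            h * np.exp(-0.5 * (((s0 - cs) / hp.sigma_s) ** 2
                               + ((z0 - cz) / hp.sigma_z) ** 2))
            for h, cs, cz in zip(hills.heights, hills.centers_s, hills.centers_z)
        )
        assert hills.bias(s0, z0)[0] == pytest.approx(expected, rel=1e-10)

    def test_bias_factor_validation(self):
        with pytest.raises(ValueError, match="γ"):
            HillsParams(bias_factor=1.0)


def test_dissipation_additivity_of_work_rule():
    """W(0→t₂) = W(0→t₁) + W(t₁→t₂) holds exactly for the discrete rule."""
    path = linear_toy_path(-1.5, 1.5, 11)
    sys1 = ToySystem(DoubleWell1D(), dim=1, thermo=T300)
    sched = SMDSchedule(k=100.0, s_start=0.0, s_end=1.0, duration=4.0)
    _, tr = smd_run(sys1, path, sched, dt=0.002, seed=21)
    k = len(tr.w_accum) // 3
    total = tr.w_accum[-1]
    parts = (tr.w_accum[k] - tr.w_accum[0]) + (total - tr.w_accum[k])
    assert parts == pytest.approx(total, abs=1e-12)
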