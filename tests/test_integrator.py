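"""Leap-frog mechanics, CFA/RESPA application, SHAKE, COM removal."""

import numpy as np
import pytest

import mtslab as m
from mtslab.integrator import MidForceCache, shake
from conftest import make_lj_liquid


def free_state(n=1, mass=1.0, box=10.0):
    ff = m.ForceField(species={"X": m.Species(
        name="X", site_names=["X"], masses=np.array([mass]),
        charges=np.array([0.0]), site_types=["X"],
        geometry=np.zeros((1, 3)))},
        lj_types={"X": (0.0, 0.0)}, r_short=1.0, r_long=1.0)
    top = m.build_topology(ff, [("X", n)])
    return m.SystemState(positions=np.zeros((n, 3)),
                         velocities=np.zeros((n, 3)),
                         box=np.full(3, box), topology=top)


class TestEffectiveMidForce:
    def _cache(self, f):
        return MidForceCache(np.asarray(f, float), 0.0, 0.0, 0.0, 0)

    def test_nm_one_both_applications_identical(self):
        cache = self._cache([[1.0, 2.0, 3.0]])
        cfa = m.effective_mid_force(cache, 0, 1, "CFA")
        respa = m.effective_mid_force(cache, 0, 1, "RESPA")
        np.testing.assert_array_equal(cfa, respa)
        np.testing.assert_array_equal(cfa, cache.forces)

    def test_cfa_repeats_cached_force(self):
        cache = self._cache([[1.0, 0.0, 0.0]])
        for step in (0, 1):
            np.testing.assert_array_equal(
                m.effective_mid_force(cache, step, 2, "CFA"), cache.forces)

    def test_respa_impulse_then_zero(self):
        cache = self._cache([[1.0, 0.0, 0.0]])
        at0 = m.effective_mid_force(cache, 0, 2, "RESPA")
        at1 = m.effective_mid_force(cache, 1, 2, "RESPA")
        np.testing.assert_array_equal(at0, 2.0 * cache.forces)
        assert np.all(at1 == 0.0)


class TestLeapfrog:
    def test_free_flight(self):
        st = free_state()
        st.velocities[0] = [1.0, 0.0, 0.0]
        zero = np.zeros((1, 3))
        m.leapfrog_step(st, zero, zero, dt=0.002)
        np.testing.assert_allclose(st.positions[0], [0.002, 0, 0])
        assert st.time == pytest.approx(0.002)

    def test_non_finite_force_reported(self):
        st = free_state()
        bad = np.array([[np.nan, 0.0, 0.0]])
        with pytest.raises(FloatingPointError, match="site 0"):
            m.leapfrog_step(st, bad, np.zeros((1, 3)), 0.002)

    def _oscillator_energy_series(self, dt, n_steps, k=10.0):
        """1D harmonic oscillator integrated with the leap-frog kick;
        returns on-step total energies (midpoint velocities)."""
        st = free_state()
        st.positions[0, 0] = 0.3
        energies = []
        for _ in range(n_steps):
            f = np.zeros((1, 3))
            f[0, 0] = -k * st.positions[0, 0]
            v_old = st.velocities.copy()
            m.leapfrog_step(st, f, np.zeros((1, 3)), dt)
            v_mid = 0.5 * (v_old + st.velocities)
            x_prev = st.positions[0, 0] - st.velocities[0, 0] * dt
            energies.append(0.5 * v_mid[0, 0] ** 2
                            + 0.5 * k * x_prev ** 2)
        return np.array(energies)

    def test_oscillator_energy_drift_free_and_dt2_scaling(self):
        """Energy oscillates without secular drift; halving dt cuts the
        RMS energy error by about 4x (second-order integrator)."""
        k = 10.0
        period = 2 * np.pi / np.sqrt(k)
        dt = period / 100
        e1 = self._oscillator_energy_series(dt, 10_000, k)
        first, last = e1[:500].mean(), e1[-500:].mean()
        assert abs(last - first) / e1.mean() < 1e-4   # no drift
        e2 = self._oscillator_energy_series(dt / 2, 20_000, k)
        rms1 = np.sqrt(np.mean((e1 - e1.mean()) ** 2))
        rms2 = np.sqrt(np.mean((e2 - e2.mean()) ** 2))
        assert 3.5 < rms1 / rms2 < 4.5

    def test_time_reversal_recovers_positions(self):
        """Kick-drift leap-frog retraces its path after one extra kick
        and velocity negation (unconstrained, unthermostatted)."""
        state, ff = make_lj_liquid(n=20, box_edge=2.2, seed=8)
        x0 = state.positions.copy()
        n = 200
        dt = 0.002
        zero = np.zeros_like(state.positions)
        for _ in range(n):
            pl = m.build_twin_pairlist(state, ff)
            rep = m.shell_forces(state, pl, "all", ff)
            m.leapfrog_step(state, rep.forces, zero, dt)
        pl = m.build_twin_pairlist(state, ff)
        rep = m.shell_forces(state, pl, "all", ff)
        state.velocities += rep.forces / state.topology.masses[:, None] * dt
        state.velocities *= -1.0
        for _ in range(n):
            pl = m.build_twin_pairlist(state, ff)
            rep = m.shell_forces(state, pl, "all", ff)
            m.leapfrog_step(state, rep.forces, zero, dt)
        assert np.max(np.abs(state.positions - x0)) < 1e-8


class TestShake:
    def test_satisfied_constraints_unchanged(self):
        ref = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        out, n_it = shake(ref, ref.copy(), np.array([[0, 1]]),
                          np.array([0.1]), np.ones(2))
        np.testing.assert_array_equal(out, ref)
        assert n_it == 0

    def test_single_constraint_closed_form(self):
        """Equal masses: both sites move symmetrically inward along the
        bond; final length within the geometric tolerance of 0.1 nm."""
        ref = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        trial = np.array([[0.0, 0, 0], [0.11, 0, 0]])
        out, _ = shake(ref, trial, np.array([[0, 1]]), np.array([0.1]),
                       np.ones(2), tol=1e-4)
        length = np.linalg.norm(out[1] - out[0])
        assert abs(length**2 - 0.01) / 0.01 <= 2e-4
        shift = trial - out
        assert shift[0, 0] == pytest.approx(-shift[1, 0], rel=1e-9)

    def test_rigid_water_after_free_flight(self, ff_desk):
        """All three distances of the rigid 3-site molecule satisfy the
        criterion after a random drift step."""
        sp = ff_desk.species["W"]
        top = m.build_topology(ff_desk, [("W", 1)])
        ref = sp.geometry + 1.0
        rng = np.random.default_rng(0)
        trial = ref + rng.normal(0, 0.01, ref.shape)
        out, _ = shake(ref, trial, top.constraints,
                       top.constraint_lengths, 1.0 / top.masses)
        for (i, j), d0 in zip(top.constraints, top.constraint_lengths):
            d2 = np.sum((out[i] - out[j]) ** 2)
            assert abs(d2 - d0**2) / d0**2 <= 2e-4

    def test_unsatisfiable_constraint_raises(self):
        ref = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        trial = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        with pytest.raises(RuntimeError, match="converge"):
            shake(ref, trial, np.array([[0, 1]]), np.array([0.1]),
                  np.ones(2), max_iter=5)


class TestComRemoval:
    def test_uniform_velocity_zeroed(self):
        st = free_state(n=4)
        st.velocities[:] = [0.5, -0.2, 0.1]
        m.remove_com_motion(st)
        assert np.all(st.velocities == 0.0)

    def test_momentum_zero_and_ke_never_increases(self):
        rng = np.random.default_rng(1)
        st = free_state(n=10)
        st.velocities = rng.normal(0, 0.5, (10, 3))
        k_before = m.kinetic_energy(st)
        m.remove_com_motion(st)
        p = np.sum(st.topology.masses[:, None] * st.velocities, axis=0)
        assert np.all(np.abs(p) < 1e-12)
        assert m.kinetic_energy(st) <= k_before


class TestDriver:
    def test_same_seed_bitwise_reproducible(self, lj_liquid_equilibrated):
        state, ff = lj_liquid_equilibrated
        cfg = m.MTSConfig(n_steps=100, scheme="TR", n_m=5, n_p=5,
                          thermostat="SD", t0=300.0, seed=42)
        a = m.run_simulation(state.copy(), ff, cfg)
        b = m.run_simulation(state.copy(), ff, cfg)
        np.testing.assert_array_equal(a.final_state.positions,
                                      b.final_state.positions)
        assert a.energy.equals(b.energy)

    def test_invalid_config_rejected(self, lj_liquid_equilibrated):
        state, ff = lj_liquid_equilibrated
        cfg = m.MTSConfig(n_steps=10, scheme="TR", n_m=3, n_p=5)
        with pytest.raises(ValueError, match="n_m = n_p"):
            m.run_simulation(state.copy(), ff, cfg)

    @pytest.mark.parametrize("thermostat", ["NH", "WC"])
    def test_single_bath_scaling_preserves_zero_momentum(
            self, lj_liquid_equilibrated, thermostat):
        """Uniform bath scaling maps zero bath momentum to zero: a
        single-species run started momentum-free stays momentum-free
        even with COM removal disabled (pair forces + scaling)."""
        state, ff = lj_liquid_equilibrated
        st = state.copy()
        m.remove_com_motion(st)
        cfg = m.MTSConfig(n_steps=200, scheme="TR", n_m=5, n_p=5,
                          thermostat=thermostat, t0=300.0,
                          com_removal_period=0.0, seed=0)
        res = m.run_simulation(st, ff, cfg)
        masses = res.final_state.topology.masses[:, None]
        p = np.abs(np.sum(masses * res.final_state.velocities, axis=0))
        assert np.all(p < 1e-8)
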