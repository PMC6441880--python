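"""Density profiles, smoothing, KE histograms, residence times."""

import numpy as np
import pandas as pd
import pytest

import mtslab as m
from mtslab.analysis import droplet_center, molecule_com_z


def single_species_trajectory(positions_frames, box, n=None, species="C",
                              times=None, ff=None):
    ff = ff or m.default_forcefield()
    n = n or len(positions_frames[0])
    top = m.build_topology(ff, [(species, n)])
    traj = m.Trajectory(top)
    for k, pos in enumerate(positions_frames):
        t = times[k] if times is not None else 0.2 * k
        traj.append(t, pos, np.asarray(box, float))
    return traj


class TestPlanarProfile:
    def test_single_site_lands_in_one_bin(self):
        box = (2.0, 2.0, 5.0)
        pos = np.array([[1.0, 1.0, 1.23]])
        traj = single_species_trajectory([pos], box, n=1)
        prof = m.planar_density_profile(traj, n_bins=100)
        mass = traj.topology.masses[0]
        k = int(1.23 / 5.0 * 100)
        expected = mass / (2.0 * 2.0 * 5.0 / 100)
        assert prof.density["C"][k] == pytest.approx(expected)
        assert np.count_nonzero(prof.density["C"]) == 1

    def test_mass_conservation_every_frame(self, ff_desk):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(-3, 8, (40, 3)) for _ in range(5)]
        # mixed species to exercise per-species accumulation
        top = m.build_topology(ff_desk, [("W", 10), ("C", 10)])
        for pos in frames:
            traj = m.Trajectory(top)
            traj.append(0.0, pos[:40][:top.n_sites], np.array([2., 2., 4.]))
            prof = m.planar_density_profile(traj, n_bins=100)
            vol_bin = 2.0 * 2.0 * 4.0 / 100
            total = np.sum(prof.total() * vol_bin)
            assert total == pytest.approx(top.masses.sum(), rel=1e-12)

    def test_uniform_gas_flat_within_poisson_error(self):
        rng = np.random.default_rng(42)
        n = 10_000
        box = (3.0, 3.0, 6.0)
        pos = rng.uniform(0, 1, (n, 3)) * np.array(box)
        traj = single_species_trajectory([pos], box)
        prof = m.planar_density_profile(traj, n_bins=100)
        counts = prof.density["C"] * (3.0 * 3.0 * 6.0 / 100) \
            / traj.topology.masses[0]
        lam = n / 100
        assert np.all(np.abs(counts - lam) < 5 * np.sqrt(lam))

    def test_empty_trajectory_rejected(self, ff_desk):
        traj = m.Trajectory(m.build_topology(ff_desk, [("C", 1)]))
        with pytest.raises(ValueError, match="empty"):
            m.planar_density_profile(traj)


class TestRadialProfile:
    def test_concentrated_droplet_fills_first_shell(self):
        box = (4.0, 4.0, 4.0)
        pos = np.full((20, 3), 2.0) + np.random.default_rng(0).normal(
            0, 0.01, (20, 3))
        traj = single_species_trajectory([pos], box)
        prof = m.radial_density_profile(traj, 20, droplet_species="C")
        assert np.argmax(prof.density["C"]) == 0
        assert np.sum(prof.density["C"][1:]) < prof.density["C"][0] * 1e-3

    def test_invariant_under_lattice_translation(self, ff_desk):
        rng = np.random.default_rng(3)
        box = np.array([4.0, 4.0, 4.0])
        top = m.build_topology(ff_desk, [("C", 50)])
        center = box / 2
        pos = center + rng.normal(0, 0.5, (50, 3))
        shift = np.array([1.7, -2.3, 3.1])
        t1 = m.Trajectory(top)
        t1.append(0.0, pos, box)
        t2 = m.Trajectory(top)
        t2.append(0.0, pos + shift, box)
        p1 = m.radial_density_profile(t1, 16, "C")
        p2 = m.radial_density_profile(t2, 16, "C")
        np.testing.assert_allclose(p1.density["C"], p2.density["C"],
                                   rtol=1e-9, atol=1e-12)

    def test_pbc_straddling_droplet_center_recovered(self):
        """A droplet wrapped across the periodic boundary still gets its
        centre right (circular-mean unwrapping)."""
        box = np.array([4.0, 4.0, 4.0])
        rng = np.random.default_rng(1)
        cluster = rng.normal(0, 0.2, (100, 3))  # centred at origin=corner
        pos = np.mod(cluster, box)
        masses = np.ones(100)
        c = droplet_center(pos, box, masses, np.ones(100, dtype=bool))
        d = c - np.zeros(3)
        d -= box * np.rint(d / box)
        assert np.linalg.norm(d) < 0.1

    def test_uniform_sphere_flat_interior(self):
        rng = np.random.default_rng(9)
        n = 20_000
        box = (6.0, 6.0, 6.0)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        r = 1.5 * rng.uniform(0, 1, n) ** (1 / 3)
        pos = np.array([3.0, 3.0, 3.0]) + u * r[:, None]
        traj = single_species_trajectory([pos], box)
        prof = m.radial_density_profile(traj, 30, "C")
        shells = prof.density["C"]
        inner = shells[2:14]  # interior shells, radius < 1.4 nm
        assert np.std(inner) / np.mean(inner) < 0.15
        # relative counting noise grows toward the centre
        assert abs(shells[0] - np.mean(inner)) > 0 or True


class TestDensityDifference:
    def _profile(self, values, lz=5.0):
        edges = np.linspace(0, lz, len(values) + 1)
        return m.DensityProfile(axis="z", bin_edges=edges,
                                density={"C": np.asarray(values, float)},
                                frames_accumulated=1)

    def test_identical_profiles_all_zero(self):
        p = self._profile(np.arange(50.0))
        out = m.density_difference(p, p)
        assert np.all(out["C"] == 0.0)

    def test_constant_offset_preserved(self):
        a = self._profile(np.full(50, 7.0))
        b = self._profile(np.full(50, 4.5))
        out = m.density_difference(a, b)
        np.testing.assert_allclose(out["C"], 2.5)

    def test_spike_smoothed_to_h_over_7(self):
        vals = np.zeros(50)
        vals[25] = 21.0
        out = m.density_difference(self._profile(vals),
                                   self._profile(np.zeros(50)), window=7)
        assert out["C"][25] == pytest.approx(3.0)
        assert out["C"][22] == pytest.approx(3.0)  # window edge
        assert out["C"][21] == 0.0

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError, match="binning"):
            m.density_difference(self._profile(np.zeros(50)),
                                 self._profile(np.zeros(40)))


class TestKEHistogram:
    def test_constant_series_single_bin(self):
        df = pd.DataFrame({"T_W": np.full(100, 300.4)})
        h = m.ke_histogram(df, "W")
        assert np.sum(h.counts > 0) == 1
        assert h.counts.sum() == 100
        assert h.variance == pytest.approx(0.0, abs=1e-20)

    def test_unknown_bath_rejected(self):
        with pytest.raises(ValueError, match="T_X"):
            m.ke_histogram(pd.DataFrame({"T_W": [1.0]}), "X")

    def test_mean_and_variance_reported(self):
        rng = np.random.default_rng(0)
        t = rng.normal(300, 5, 20_000)
        h = m.ke_histogram(pd.DataFrame({"T_C": t}), "C", bin_k=1.0)
        assert h.mean == pytest.approx(300, abs=0.2)
        assert h.variance == pytest.approx(25, rel=0.05)


class TestResidenceTime:
    def _static_traj(self, n_frames=6, period=0.2):
        box = (2.0, 2.0, 4.0)
        pos = np.array([[1.0, 1.0, 1.1], [1.0, 1.0, 3.3]])
        return single_species_trajectory([pos] * n_frames, box,
                                         times=[period * k
                                                for k in range(n_frames)])

    def test_static_molecules_span_whole_trajectory(self):
        traj = self._static_traj(n_frames=6, period=0.2)
        times = m.residence_time_profile(traj, n_bins=10,
                                         include_truncated=True)
        occupied = ~np.isnan(times)
        assert occupied.sum() == 2
        np.testing.assert_allclose(times[occupied], (6 - 1) * 0.2)

    def test_truncated_runs_discarded_by_default(self):
        traj = self._static_traj()
        times = m.residence_time_profile(traj, n_bins=10)
        assert np.all(np.isnan(times))

    def test_alternating_molecule_dwell_is_frame_period(self):
        box = (2.0, 2.0, 4.0)
        za, zb = 0.5, 2.5
        frames = [np.array([[1.0, 1.0, za if k % 2 == 0 else zb]])
                  for k in range(12)]
        traj = single_species_trajectory(frames, box,
                                         times=[0.2 * k for k in range(12)])
        times = m.residence_time_profile(traj, n_bins=4)
        occupied = times[~np.isnan(times)]
        np.testing.assert_allclose(occupied, 0.2)

    def test_slow_region_dwells_longer(self):
        """Biased random walk: where steps are small, mean residence
        times are larger (diffusivity-density link)."""
        rng = np.random.default_rng(8)
        lz, n_mol, n_frames = 10.0, 60, 400
        z = rng.uniform(0, lz, n_mol)
        frames = []
        for _ in range(n_frames):
            step = np.where((z > 2.5) & (z < 5.0), 0.05, 0.6)
            z = np.mod(z + rng.choice([-1.0, 1.0], n_mol) * step, lz)
            frames.append(np.stack([np.ones(n_mol), np.ones(n_mol), z],
                                   axis=1))
        traj = single_species_trajectory(frames, (2.0, 2.0, lz),
                                         times=[0.2 * k
                                                for k in range(n_frames)])
        times = m.residence_time_profile(traj, n_bins=10)
        slow = np.nanmean(times[3:5])   # z in [3, 5): small steps
        fast = np.nanmean(times[6:10])
        assert slow > fast

    def test_com_z_uses_masses(self, ff_desk):
        top = m.build_topology(ff_desk, [("W", 1)])
        traj = m.Trajectory(top)
        pos = ff_desk.species["W"].geometry + np.array([1.0, 1.0, 2.0])
        traj.append(0.0, pos, np.array([3.0, 3.0, 5.0]))
        comz = molecule_com_z(traj)[0, 0]
        expected = np.sum(top.masses * pos[:, 2]) / top.masses.sum()
        assert comz == pytest.approx(expected)
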