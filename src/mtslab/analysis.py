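"""Trajectory post-processing: density profiles, KE histograms, residence.

All operations are pure functions of their inputs; re-running an
analysis on the same trajectory reproduces its output bit-identically.
Densities are site-mass based (each site's mass goes to the bin holding
its wrapped coordinate), which conserves the total system mass exactly
per frame; residence times use molecular centres of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB
from .core import Topology, degrees_of_freedom
from .trajectory import Trajectory

#: 1 u/nm^3 in kg/m^3
U_PER_NM3_TO_KG_M3 = 1.66053907


@dataclass
class DensityProfile:
    """Per-species mass density over z-bins or radial shells."""

    axis: str                       # "z" | "r"
    bin_edges: np.ndarray           # (n_bins + 1,) nm
    density: dict[str, np.ndarray]  # species -> (n_bins,) u nm^-3
    frames_accumulated: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total(self) -> np.ndarray:
        return np.sum(list(self.density.values()), axis=0)

    def in_si(self) -> dict[str, np.ndarray]:
        """Densities converted to kg/m^3."""
        return {k: v * U_PER_NM3_TO_KG_M3 for k, v in self.density.items()}

    def to_frame(self) -> pd.DataFrame:
        data = {self.axis: self.bin_centers}
        data.update({f"rho_{k}": v for k, v in self.density.items()})
        return pd.DataFrame(data)


@dataclass
class KEHistogram:
    """Histogram of instantaneous bath kinetic temperature."""

    bath: str
    bin_edges: np.ndarray           # K
    counts: np.ndarray
    mean: float                     # K
    variance: float                 # K^2

    @property
    def normalized(self) -> np.ndarray:
        width = np.diff(self.bin_edges)
        total = np.sum(self.counts * width)
        return self.counts / total if total > 0 else self.counts


def _species_masks(top: Topology, species) -> dict[str, np.ndarray]:
    names = list(top.species_names) if species is None else list(species)
    return {name: top.species_site_mask(name) for name in names}


def planar_density_profile(traj: Trajectory, n_bins: int = 100,
                           species=None,
                           recenter: str | None = None) -> DensityProfile:
    """Mass density from equidistant bins along z, frame-averaged.

    Coordinates are wrapped into [0, L_z); for varying-box (NPT-in-xy)
    trajectories the per-frame bin volume is used, so the profile stays
    normalized frame by frame.

    ``recenter`` names a species whose per-frame mass centre (computed
    with PBC-aware circular averaging) is shifted to L_z/2 before
    binning.  For films that drift inside vacuum margins this removes
    the slab translation, which would otherwise smear the interface
    over the frame average.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    masks = _species_masks(top, species)
    rmask = top.species_site_mask(recenter) if recenter else None
    lz = traj.boxes[0][2]
    for b in traj.boxes:
        if not np.isclose(b[2], lz):
            raise ValueError("z box length must be constant across frames")
    edges = np.linspace(0.0, lz, n_bins + 1)
    acc = {k: np.zeros(n_bins) for k in masks}
    for pos, box in zip(traj.positions, traj.boxes):
        vol_bin = box[0] * box[1] * lz / n_bins
        zc = pos[:, 2]
        if rmask is not None:
            center = droplet_center(pos, box, top.masses, rmask)
            zc = zc - center[2] + lz / 2.0
        z = np.mod(zc, lz)
        idx = np.minimum((z / lz * n_bins).astype(int), n_bins - 1)
        for name, mask in masks.items():
            acc[name] += np.bincount(idx[mask],
                                     weights=top.masses[mask],
                                     minlength=n_bins) / vol_bin
    dens = {k: v / traj.n_frames for k, v in acc.items()}
    return DensityProfile(axis="z", bin_edges=edges, density=dens,
                          frames_accumulated=traj.n_frames)


def droplet_center(pos: np.ndarray, box: np.ndarray, masses: np.ndarray,
                   mask: np.ndarray) -> np.ndarray:
    """PBC-aware centre of mass of the droplet species.

    Each axis is unwrapped by the circular-mean trick (map coordinates to
    angles, average the unit vectors, map the mean angle back), which
    shifts the centre correctly even when the droplet straddles a
    periodic boundary.
    """
    m = masses[mask][:, None]
    theta = 2.0 * np.pi * pos[mask] / box
    sin = np.sum(m * np.sin(theta), axis=0)
    cos = np.sum(m * np.cos(theta), axis=0)
    angle = np.arctan2(-sin, -cos) + np.pi     # mean angle in [0, 2 pi)
    return angle / (2.0 * np.pi) * box


def radial_density_profile(traj: Trajectory, n_shells: int,
                           droplet_species: str,
                           species=None) -> DensityProfile:
    """Mass density in concentric shells around the droplet centre.

    The centre is re-estimated per frame from the droplet species with
    PBC unwrapping; shell k has volume (4/3) pi (r_{k+1}^3 - r_k^3) and
    the outermost edge is half the smallest box edge.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    if droplet_species not in top.species_names:
        raise ValueError(f"unknown droplet species {droplet_species!r}")
    masks = _species_masks(top, species)
    dmask = top.species_site_mask(droplet_species)
    r_max = float(np.min(traj.boxes[0])) / 2.0
    edges = np.linspace(0.0, r_max, n_shells + 1)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    acc = {k: np.zeros(n_shells) for k in masks}
    for pos, box in zip(traj.positions, traj.boxes):
        center = droplet_center(pos, box, top.masses, dmask)
        d = pos - center
        d -= box * np.rint(d / box)
        r = np.linalg.norm(d, axis=1)
        idx = np.minimum((r / r_max * n_shells).astype(int), n_shells - 1)
        within = r < r_max
        for name, mask in masks.items():
            sel = mask & within
            acc[name] += np.bincount(idx[sel], weights=top.masses[sel],
                                     minlength=n_shells) / vol
    dens = {k: v / traj.n_frames for k, v in acc.items()}
    return DensityProfile(axis="r", bin_edges=edges, density=dens,
                          frames_accumulated=traj.n_frames)


def running_average(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered moving average; the window shrinks near the edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.mean(values[lo:hi])
    return out


def density_difference(profile: DensityProfile, ref: DensityProfile,
                       window: int = 7) -> dict[str, np.ndarray]:
    """Per-bin density differences, smoothed by a running average."""
    if (len(profile.bin_edges) != len(ref.bin_edges)
            or not np.allclose(profile.bin_edges, ref.bin_edges)):
        raise ValueError("profiles have mismatched binning")
    out = {}
    for name, rho in profile.density.items():
        if name not in ref.density:
            raise ValueError(f"species {name!r} missing from reference")
        out[name] = running_average(rho - ref.density[name], window)
    return out


def ke_histogram(energy: pd.DataFrame, bath: str,
                 bin_k: float = 1.0) -> KEHistogram:
    """Histogram of a bath's instantaneous temperature with 1 K bins."""
    col = f"T_{bath}"
    if col not in energy.columns:
        raise ValueError(f"energy series has no column {col!r}")
    t = energy[col].to_numpy()
    lo = np.floor(t.min() / bin_k) * bin_k
    hi = np.ceil(t.max() / bin_k) * bin_k
    if hi <= lo:
        hi = lo + bin_k
    edges = np.arange(lo, hi + bin_k / 2, bin_k)
    counts, _ = np.histogram(t, bins=edges)
    return KEHistogram(bath=bath, bin_edges=edges, counts=counts,
                       mean=float(np.mean(t)), variance=float(np.var(t)))


def canonical_temperature_variance(top: Topology, bath: str,
                                   t0: float) -> float:
    """Canonical variance of the instantaneous bath temperature.

    From Var(K) = N_f (k_B T0)^2 / 2 and T = 2K/(N_f k_B):
    Var(T) = 2 T0^2 / N_f.
    """
    nf = degrees_of_freedom(top, bath, com_removed=False)
    return 2.0 * t0**2 / nf


def molecule_com_z(traj: Trajectory) -> np.ndarray:
    """(n_frames, n_molecules) molecular centre-of-mass z coordinates."""
    top = traj.topology
    mass_mol = np.zeros(top.n_molecules)
    np.add.at(mass_mol, top.site_molecule, top.masses)
    out = np.empty((traj.n_frames, top.n_molecules))
    for f, pos in enumerate(traj.positions):
        mz = np.zeros(top.n_molecules)
        np.add.at(mz, top.site_molecule, top.masses * pos[:, 2])
        out[f] = mz / mass_mol
    return out


def residence_time_profile(traj: Trajectory, n_bins: int = 100,
                           include_truncated: bool = False) -> np.ndarray:
    """Mean molecular residence time per z-bin, ps.

    For every molecule the maximal contiguous runs of frames whose COM z
    falls in one bin are collected; a completed run of k frames (entry
    and exit both observed) dwells k * frame_period.  Runs touching the
    trajectory ends have unknown entry/exit and are discarded unless
    ``include_truncated``, in which case they contribute their observed
    span (k - 1) * frame_period.  Bins never visited report NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames for residence times")
    period = traj.frame_period()
    lz = traj.boxes[0][2]
    z = np.mod(molecule_com_z(traj), lz)
    idx = np.minimum((z / lz * n_bins).astype(int), n_bins - 1)
    total = np.zeros(n_bins)
    count = np.zeros(n_bins)
    n_frames, n_mol = idx.shape
    for mol in range(n_mol):
        series = idx[:, mol]
        start = 0
        for f in range(1, n_frames + 1):
            if f == n_frames or series[f] != series[start]:
                k = f - start
                truncated = (start == 0) or (f == n_frames)
                if not truncated:
                    total[series[start]] += k * period
                    count[series[start]] += 1
                elif include_truncated and k >= 2:
                    total[series[start]] += (k - 1) * period
                    count[series[start]] += 1
                start = f
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)
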