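"""Synthetic two-phase system builder (planar layers and droplets).

Builds desk-scale analogues of polar/apolar solvent interfaces: a rigid
3-site polar solvent ("W") and a single-site apolar Lennard-Jones
solvent ("C") placed on jittered lattices in disjoint regions — a
polar/apolar slab stack for the layer geometry, an apolar sphere in a
polar bath for the droplet geometry — with Maxwell-Boltzmann velocities
at the requested temperature and the centre-of-mass motion removed.

Initial lattice densities are chosen below the target liquid densities
so that every *intermolecular* site distance is at least 0.25 nm at
t = 0 for arbitrary shared molecular orientation; a short single-range
equilibration run then relaxes the slabs to liquid structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import KB
from .core import SystemState, Topology, build_topology
from .forcefield import ForceField

#: hard floor for intermolecular site distances at build time, nm
OVERLAP_FLOOR = 0.25

#: uniform placement jitter amplitude per coordinate, nm
JITTER = 0.02

#: gap between the lattice regions of different species, nm
REGION_GAP = 0.35

#: per-species lattice spacings, nm (W anisotropic: its rigid triangle
#: lies in the x-y plane, so in-plane spacing must absorb the H-H extent)
LATTICE_SPACING = {"W": (0.50, 0.50, 0.32), "C": (0.40, 0.40, 0.40)}

#: extra radial clearance between droplet surface and polar lattice, nm
DROPLET_GAP = 0.45


@dataclass
class SystemSpec:
    """Recipe for one synthetic two-phase system."""

    geometry: str               # "layer" | "droplet"
    n_polar: int
    n_apolar: int
    box: tuple[float, float, float]
    droplet_radius: float | None = None   # nm, droplet only
    t_init: float = 300.0       # K
    seed: int = 0
    polar_species: str = "W"
    apolar_species: str = "C"


def draw_maxwell_boltzmann(masses: np.ndarray, t: float,
                           seed: int | np.random.Generator) -> np.ndarray:
    """Per-site velocities ~ Normal(0, k_B T / m) with zero total momentum."""
    if t < 0:
        raise ValueError(f"temperature must be >= 0, got {t}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    masses = np.asarray(masses, dtype=float)
    if t == 0.0:
        return np.zeros((len(masses), 3))
    sigma = np.sqrt(KB * t / masses)
    v = rng.standard_normal((len(masses), 3)) * sigma[:, None]
    p = np.sum(masses[:, None] * v, axis=0)
    return v - p / np.sum(masses)


def _lattice_counts(box_xy: tuple[float, float],
                    spacing: tuple[float, ...]) -> tuple[int, int]:
    nx = int(np.floor(box_xy[0] / spacing[0]))
    ny = int(np.floor(box_xy[1] / spacing[1]))
    if nx < 1 or ny < 1:
        raise ValueError("box cross-section smaller than one lattice cell")
    return nx, ny


def _slab_points(n: int, box: np.ndarray, spacing: tuple[float, ...],
                 z_start: float, z_max: float, rng: np.random.Generator,
                 what: str) -> tuple[np.ndarray, float]:
    """First-n points of a jittered lattice filling a slab from z_start up."""
    nx, ny = _lattice_counts((box[0], box[1]), spacing)
    per_layer = nx * ny
    n_layers = int(np.ceil(n / per_layer))
    thickness = n_layers * spacing[2]
    if z_start + thickness > z_max:
        max_layers = int(np.floor((z_max - z_start) / spacing[2]))
        raise ValueError(
            f"box too small for {n} {what} molecules; at most "
            f"{max_layers * per_layer} fit in the available slab")
    ax, ay = box[0] / nx, box[1] / ny
    pts = []
    for iz in range(n_layers):
        for iy in range(ny):
            for ix in range(nx):
                if len(pts) == n:
                    break
                pts.append([(ix + 0.5) * ax, (iy + 0.5) * ay,
                            z_start + (iz + 0.5) * spacing[2]])
    pts = np.array(pts)
    pts += rng.uniform(-JITTER, JITTER, size=pts.shape)
    return pts, thickness


def _place_molecules(centers: np.ndarray, geometry: np.ndarray) -> np.ndarray:
    """Replicate the rigid local geometry at every lattice center."""
    return (centers[:, None, :] + geometry[None, :, :]).reshape(-1, 3)


def _check_overlap(positions: np.ndarray, site_molecule: np.ndarray,
                   box: np.ndarray) -> None:
    wrapped = np.mod(positions, box)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(OVERLAP_FLOOR, output_type="ndarray")
    if len(pairs):
        inter = site_molecule[pairs[:, 0]] != site_molecule[pairs[:, 1]]
        if np.any(inter):
            raise RuntimeError(
                "builder produced intermolecular site contacts below "
                f"{OVERLAP_FLOOR} nm")


def _assemble(ff: ForceField, spec: SystemSpec, polar_centers: np.ndarray,
              apolar_centers: np.ndarray,
              rng: np.random.Generator) -> SystemState:
    blocks = []
    parts = []
    if len(polar_centers):
        blocks.append((spec.polar_species, len(polar_centers)))
        parts.append(_place_molecules(
            polar_centers, ff.species[spec.polar_species].geometry))
    if len(apolar_centers):
        blocks.append((spec.apolar_species, len(apolar_centers)))
        parts.append(_place_molecules(
            apolar_centers, ff.species[spec.apolar_species].geometry))
    if not blocks:
        raise ValueError("empty system requested")
    top = build_topology(ff, blocks)
    positions = np.concatenate(parts, axis=0)
    box = np.asarray(spec.box, dtype=float)
    _check_overlap(positions, top.site_molecule, box)
    velocities = draw_maxwell_boltzmann(top.masses, spec.t_init, rng)
    return SystemState(positions=positions, velocities=velocities,
                       box=box, topology=top)


def build_layer(spec: SystemSpec, ff: ForceField) -> SystemState:
    """Planar two-slab system: polar slab below, apolar slab above.

    The stack is centered in z; any leftover z-extent is vacuum, so the
    film has one polar/apolar interface in the box interior plus free
    surfaces.  Deterministic for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    sp_p = LATTICE_SPACING[spec.polar_species]
    sp_a = LATTICE_SPACING[spec.apolar_species]

    def thickness(n, sp):
        if n == 0:
            return 0.0
        nx, ny = _lattice_counts((box[0], box[1]), sp)
        return int(np.ceil(n / (nx * ny))) * sp[2]

    t_p = thickness(spec.n_polar, sp_p)
    t_a = thickness(spec.n_apolar, sp_a)
    gap = REGION_GAP if (spec.n_polar and spec.n_apolar) else 0.0
    total = t_p + t_a + gap
    if total > box[2]:
        def capacity(sp, z_avail):
            nx, ny = _lattice_counts((box[0], box[1]), sp)
            return max(0, int(np.floor(z_avail / sp[2]))) * nx * ny

        max_p = capacity(sp_p, box[2] - gap - t_a)
        max_a = capacity(sp_a, box[2] - gap - t_p)
        raise ValueError(
            f"box z-edge {box[2]} nm too small for the slab stack "
            f"({total:.2f} nm); at most {max_p} polar (keeping "
            f"{spec.n_apolar} apolar) or at most {max_a} apolar "
            f"(keeping {spec.n_polar} polar) molecules fit")
    z0 = 0.5 * (box[2] - total)
    polar_centers = np.zeros((0, 3))
    apolar_centers = np.zeros((0, 3))
    if spec.n_polar:
        polar_centers, _ = _slab_points(spec.n_polar, box, sp_p, z0,
                                        z0 + t_p, rng, "polar")
    if spec.n_apolar:
        apolar_centers, _ = _slab_points(spec.n_apolar, box, sp_a,
                                         z0 + t_p + gap, box[2], rng,
                                         "apolar")
    return _assemble(ff, spec, polar_centers, apolar_centers, rng)


def build_droplet(spec: SystemSpec, ff: ForceField) -> SystemState:
    """Apolar droplet at the box center, polar solvent filling the rest."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    r = spec.droplet_radius
    if r is None:
        raise ValueError("droplet geometry requires droplet_radius")
    if r >= float(np.min(box)) / 2.0:
        raise ValueError(
            f"droplet radius {r} nm must be smaller than half the "
            f"smallest box edge ({float(np.min(box)) / 2.0:.3f} nm)")
    center = box / 2.0
    sp_a = LATTICE_SPACING[spec.apolar_species]
    sp_p = LATTICE_SPACING[spec.polar_species]

    def grid(sp):
        ns = [max(1, int(np.floor(box[d] / sp[d]))) for d in range(3)]
        axes = [(np.arange(ns[d]) + 0.5) * (box[d] / ns[d])
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    pts_a = grid(sp_a)
    dist_a = np.linalg.norm(pts_a - center, axis=1)
    inside = pts_a[dist_a <= r]
    if len(inside) < spec.n_apolar:
        raise ValueError(
            f"droplet of radius {r} nm holds at most {len(inside)} apolar "
            f"molecules, {spec.n_apolar} requested")
    order = np.argsort(np.linalg.norm(inside - center, axis=1))
    apolar_centers = inside[order[:spec.n_apolar]]

    pts_p = grid(sp_p)
    dist_p = np.linalg.norm(pts_p - center, axis=1)
    outside = pts_p[dist_p > r + DROPLET_GAP]
    if len(outside) < spec.n_polar:
        raise ValueError(
            f"box holds at most {len(outside)} polar molecules outside "
            f"the droplet, {spec.n_polar} requested")
    polar_centers = outside[rng.permutation(len(outside))[:spec.n_polar]]

    apolar_centers = apolar_centers + rng.uniform(
        -JITTER, JITTER, size=apolar_centers.shape)
    polar_centers = polar_centers + rng.uniform(
        -JITTER, JITTER, size=polar_centers.shape)
    return _assemble(ff, spec, polar_centers, apolar_centers, rng)


def topology_summary(state: SystemState):
    """Per-species table: molecules, sites, constraints, mass, charge."""
    import pandas as pd
    top = state.topology
    rows = []
    for sid, name in enumerate(top.species_names):
        mmask = top.molecule_species == sid
        smask = top.species_site_mask(name)
        rows.append({
            "species": name,
            "n_molecules": int(np.sum(mmask)),
            "n_sites": int(np.sum(smask)),
            "n_constraints": top.n_constraints_in(name),
            "total_mass_u": float(np.sum(top.masses[smask])),
            "total_charge_e": float(np.sum(top.charges[smask])),
        })
    return pd.DataFrame(rows)


def build_system(spec: SystemSpec, ff: ForceField) -> SystemState:
    if spec.geometry == "layer":
        return build_layer(spec, ff)
    if spec.geometry == "droplet":
        return build_droplet(spec, ff)
    raise ValueError(f"unknown geometry {spec.geometry!r}")
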