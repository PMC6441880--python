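"""Core simulation state, run configuration, and kinetic observables.

Unit system: nm, ps, u, e, kJ/mol, K (GROMOS convention); see
:mod:`mtslab.constants`.  Velocities live on the half-step time grid
``t - dt/2`` as required by leap-frog integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB
from .forcefield import ForceField


@dataclass
class Topology:
    """Flattened site/molecule/species bookkeeping for one system.

    Built once from a force field and an ordered list of
    ``(species_name, count)`` blocks; all per-site arrays are congruent
    with the position array of the states that share this topology.
    """

    species_names: list[str]            # distinct species, index = species id
    molecule_species: np.ndarray        # (M,) species id per molecule
    site_molecule: np.ndarray           # (N,) molecule index per site
    first_site: np.ndarray              # (M,) first site index per molecule
    sites_per_molecule: np.ndarray      # (M,)
    masses: np.ndarray                  # (N,) u
    charges: np.ndarray                 # (N,) e
    site_type_index: np.ndarray         # (N,) row into the LJ tables
    type_names: list[str]
    constraints: np.ndarray             # (K, 2) int site pairs
    constraint_lengths: np.ndarray      # (K,) nm

    @property
    def n_sites(self) -> int:
        return len(self.masses)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_species)

    def species_site_mask(self, bath: str) -> np.ndarray:
        """Boolean site mask for ``bath`` = a species name or ``"all"``."""
        if bath == "all":
            return np.ones(self.n_sites, dtype=bool)
        if bath not in self.species_names:
            raise ValueError(f"unknown bath {bath!r}; "
                             f"known: {self.species_names + ['all']}")
        sid = self.species_names.index(bath)
        return self.molecule_species[self.site_molecule] == sid

    def species_molecule_mask(self, bath: str) -> np.ndarray:
        if bath == "all":
            return np.ones(self.n_molecules, dtype=bool)
        sid = self.species_names.index(bath)
        return self.molecule_species == sid

    def n_constraints_in(self, bath: str) -> int:
        if len(self.constraints) == 0:
            return 0
        mask = self.species_site_mask(bath)
        return int(np.sum(mask[self.constraints[:, 0]]))


def build_topology(ff: ForceField,
                   blocks: list[tuple[str, int]]) -> Topology:
    """Assemble a :class:`Topology` from ordered species blocks."""
    _, _, type_index = ff.lj_tables()
    mol_species: list[int] = []
    site_mol: list[int] = []
    first: list[int] = []
    nsites: list[int] = []
    masses: list[float] = []
    charges: list[float] = []
    stype: list[int] = []
    cons: list[tuple[int, int]] = []
    clen: list[float] = []
    names = sorted({name for name, _ in blocks},
                   key=[b[0] for b in blocks].index)
    mol = 0
    site = 0
    for name, count in blocks:
        sp = ff.species[name]
        sid = names.index(name)
        for _ in range(count):
            mol_species.append(sid)
            first.append(site)
            nsites.append(sp.n_sites)
            for k in range(sp.n_sites):
                site_mol.append(mol)
                masses.append(sp.masses[k])
                charges.append(sp.charges[k])
                stype.append(type_index[sp.site_types[k]])
            for i, j, d in sp.constraints:
                cons.append((first[-1] + i, first[-1] + j))
                clen.append(d)
            site += sp.n_sites
            mol += 1
    return Topology(
        species_names=names,
        molecule_species=np.array(mol_species, dtype=np.int64),
        site_molecule=np.array(site_mol, dtype=np.int64),
        first_site=np.array(first, dtype=np.int64),
        sites_per_molecule=np.array(nsites, dtype=np.int64),
        masses=np.array(masses),
        charges=np.array(charges),
        site_type_index=np.array(stype, dtype=np.int64),
        type_names=ff.type_names(),
        constraints=np.array(cons, dtype=np.int64).reshape(-1, 2),
        constraint_lengths=np.array(clen),
    )


@dataclass
class SystemState:
    """Positions, half-step velocities, periodic box, and the clock.

    ``velocities`` are staggered at ``time - dt/2``.  Positions may drift
    outside ``[0, L)``; the minimum-image convention is applied wherever
    distances are computed, so molecules stay whole in memory.
    """

    positions: np.ndarray       # (N, 3) nm
    velocities: np.ndarray      # (N, 3) nm/ps at t - dt/2
    box: np.ndarray             # (3,) nm, orthorhombic edge lengths
    topology: Topology
    time: float = 0.0           # ps
    step: int = 0

    def copy(self) -> "SystemState":
        return replace(self, positions=self.positions.copy(),
                       velocities=self.velocities.copy(),
                       box=self.box.copy())

    def validate(self) -> list[str]:
        out = []
        if np.any(self.box <= 0):
            out.append("all box edges must be > 0")
        if self.positions.shape != self.velocities.shape:
            out.append("velocities must be congruent with positions")
        if self.positions.shape[0] != self.topology.n_sites:
            out.append("positions inconsistent with topology site count")
        return out


@dataclass
class MTSConfig:
    """Run configuration: time stepping, scheme, couplers, outputs.

    scheme ``"SR"`` evaluates all nonbonded forces within ``r_long`` every
    step from a pairlist rebuilt every ``n_p`` steps; ``"TR"`` splits
    forces at ``r_short`` and refreshes the mid shell every ``n_m`` steps,
    applied either as constant forces (``"CFA"``) or impulses
    (``"RESPA"``).
    """

    dt: float = 0.002               # ps, inner time step
    n_steps: int = 1000
    n_m: int = 1                    # mid-range force update period, steps
    n_p: int = 1                    # pairlist update period, steps
    scheme: str = "SR"              # SR | TR
    application: str = "CFA"        # CFA | RESPA
    thermostat: str = "none"        # none | WC | NH | NHchain | SD
    tau_t: float = 0.1              # ps, WC/NH coupling time
    chain_length: int = 3           # NHchain
    gamma: float = 10.0             # ps^-1, SD friction
    t0: dict[str, float] | float = 300.0   # target T per bath (or common)
    barostat: str = "none"          # none | berendsen-xy
    tau_b: float = 0.5              # ps
    p0: float = 1.0                 # bar
    kappa: float = 4.5e-5           # bar^-1, isothermal compressibility
    com_removal_period: float = 1.0  # ps; 0 disables
    seed: int = 0
    traj_period: float = 0.2        # ps
    energy_period: float = 0.1      # ps

    def t0_for(self, bath: str) -> float:
        if isinstance(self.t0, dict):
            return self.t0[bath]
        return float(self.t0)


def validate_config(cfg: MTSConfig, ff: ForceField) -> list[str]:
    """Check scheme definitions and coupler parameters; return violations.

    The single-range scheme requires ``n_m = 1`` (all forces within
    ``R_l`` every step); the twin-range scheme requires ``R_s < R_l`` and
    ``n_m = n_p > 1`` so that mid-range forces and pairlists refresh
    together.
    """
    out = list(ff.validate())
    if cfg.dt <= 0:
        out.append(f"dt must be > 0, got {cfg.dt}")
    if cfg.n_m < 1 or cfg.n_p < 1:
        out.append(f"n_m and n_p must be >= 1, got n_m={cfg.n_m}, "
                   f"n_p={cfg.n_p}")
    if cfg.scheme == "SR":
        if cfg.n_m != 1:
            out.append(f"SR requires n_m = 1, got n_m={cfg.n_m}")
    elif cfg.scheme == "TR":
        if cfg.n_m != cfg.n_p:
            out.append(f"TR requires n_m = n_p, got n_m={cfg.n_m}, "
                       f"n_p={cfg.n_p}")
        # the degenerate TR setups R_s = R_l (empty mid shell) and
        # n_m = 1 (SR-equivalent) remain runnable on purpose: they are
        # the scheme-identity checks of the twin-range machinery
    else:
        out.append(f"unknown scheme {cfg.scheme!r}")
    if cfg.application not in ("CFA", "RESPA"):
        out.append(f"unknown mid-force application {cfg.application!r}")
    if cfg.thermostat not in ("none", "WC", "NH", "NHchain", "SD"):
        out.append(f"unknown thermostat {cfg.thermostat!r}")
    if cfg.thermostat in ("WC", "NH", "NHchain") and cfg.tau_t <= 0:
        out.append(f"tau_t must be > 0 with thermostat {cfg.thermostat}")
    if cfg.thermostat == "NHchain" and cfg.chain_length < 2:
        out.append("NHchain requires chain_length >= 2")
    if cfg.thermostat == "SD" and cfg.gamma < 0:
        out.append("SD friction gamma must be >= 0")
    if cfg.barostat not in ("none", "berendsen-xy"):
        out.append(f"unknown barostat {cfg.barostat!r}")
    if cfg.barostat != "none" and cfg.tau_b <= 0:
        out.append("tau_b must be > 0 when the barostat is enabled")
    return out


def kinetic_energy(state: SystemState, bath: str = "all") -> float:
    """Half-step kinetic energy of a bath, kJ/mol: K = 1/2 sum m v^2."""
    mask = state.topology.species_site_mask(bath)
    if not np.any(mask):
        raise ValueError(f"bath {bath!r} selects no sites")
    v = state.velocities[mask]
    m = state.topology.masses[mask]
    return float(0.5 * np.sum(m * np.sum(v * v, axis=1)))


def degrees_of_freedom(topology: Topology, bath: str = "all",
                       com_removed: bool = True) -> int:
    """Number of kinetic degrees of freedom in a bath.

    3 per site minus the constraints internal to the bath; the 3 removed
    centre-of-mass degrees of freedom are charged to the all-atoms bath
    only (per-species baths keep all 3N - K of theirs).
    """
    mask = topology.species_site_mask(bath)
    n = int(np.sum(mask))
    if n == 0:
        raise ValueError(f"bath {bath!r} selects no sites")
    nf = 3 * n - topology.n_constraints_in(bath)
    if bath == "all" and com_removed:
        nf -= 3
    return nf


def instantaneous_temperature(state: SystemState, bath: str = "all",
                              com_removed: bool = True) -> float:
    """Instantaneous bath temperature T = 2K / (N_f k_B), K."""
    k = kinetic_energy(state, bath)
    nf = degrees_of_freedom(state.topology, bath, com_removed)
    return 2.0 * k / (nf * KB)
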