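"""Shared fixtures: small systems, equilibrated liquids, force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import mtslab as m


@pytest.fixture(scope="session")
def ff_std() -> m.ForceField:
    """Standard cutoffs 0.8/1.4 nm (needs boxes > 2.8 nm)."""
    return m.default_forcefield()


@pytest.fixture(scope="session")
def ff_desk() -> m.ForceField:
    """Desk-scale cutoffs 0.6/1.0 nm for the (2.2, 2.2, 6.6) nm box."""
    return m.default_forcefield(r_short=0.6, r_long=1.0)


def make_lj_liquid(n: int = 50, box_edge: float = 2.4, seed: int = 0,
                   t_init: float = 300.0,
                   ff: m.ForceField | None = None) -> tuple:
    """Apolar LJ liquid cube (no constraints, no charges)."""
    ff = ff or m.default_forcefield(r_short=0.6, r_long=1.0)
    spec = m.SystemSpec("layer", n_polar=0, n_apolar=n,
                        box=(box_edge, box_edge, box_edge), seed=seed,
                        t_init=t_init)
    return m.build_layer(spec, ff), ff


@pytest.fixture(scope="session")
def lj_liquid_equilibrated() -> tuple:
    """50-molecule LJ liquid relaxed for 5 ps (shared, do not mutate)."""
    state, ff = make_lj_liquid(n=50, box_edge=2.4, seed=3)
    state = m.equilibrate(state, ff, t_sim=5.0, t0=300.0, seed=3)
    return state, ff


@pytest.fixture(scope="session")
def small_layer_equilibrated(ff_desk) -> m.SystemState:
    """Small two-phase layer (60 W + 20 C) relaxed for 5 ps (shared)."""
    spec = m.SystemSpec("layer", n_polar=60, n_apolar=20,
                        box=(2.2, 2.2, 4.4), seed=7)
    state = m.build_layer(spec, ff_desk)
    return m.equilibrate(state, ff_desk, t_sim=5.0, t0=300.0, seed=7)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately plain Python/numpy)

def oracle_min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def oracle_pairlists(state: m.SystemState, ff: m.ForceField):
    """All-pairs double loop over molecule centers of geometry."""
    top = state.topology
    centers = []
    for mol in range(top.n_molecules):
        f = top.first_site[mol]
        n = top.sites_per_molecule[mol]
        centers.append(state.positions[f:f + n].mean(axis=0))
    short, mid = [], []
    for i in range(top.n_molecules):
        for j in range(i + 1, top.n_molecules):
            d = oracle_min_image(centers[i] - centers[j], state.box)
            r = np.sqrt(np.dot(d, d))
            if r <= ff.r_short:
                short.append((i, j))
            elif r <= ff.r_long:
                mid.append((i, j))
    return set(short), set(mid)


def oracle_shell_forces(state: m.SystemState, pairs, ff: m.ForceField):
    """Site-by-site LJ + reaction-field sums over given molecule pairs."""
    top = state.topology
    forces = np.zeros_like(state.positions)
    e_lj = 0.0
    e_coul = 0.0
    crf = 2.0 * (ff.eps_rf - 1.0) / (2.0 * ff.eps_rf + 1.0)
    rl = ff.r_long
    for (mi, mj) in pairs:
        fi, ni = top.first_site[mi], top.sites_per_molecule[mi]
        fj, nj = top.first_site[mj], top.sites_per_molecule[mj]
        for i in range(fi, fi + ni):
            for j in range(fj, fj + nj):
                d = oracle_min_image(state.positions[i]
                                     - state.positions[j], state.box)
                r = np.sqrt(np.dot(d, d))
                ta = top.type_names[top.site_type_index[i]]
                tb = top.type_names[top.site_type_index[j]]
                c6, c12 = ff.lj_pair_params(ta, tb)
                e_lj += c12 / r**12 - c6 / r**6
                fmag = (12 * c12 / r**13 - 6 * c6 / r**7) / r
                qq = ff.coulomb_constant * top.charges[i] * top.charges[j]
                e_coul += qq * (1 / r + crf * r**2 / (2 * rl**3)
                                - (1 + crf / 2) / rl)
                fmag += qq * (1 / r**3 - crf / rl**3)
                forces[i] += fmag * d
                forces[j] -= fmag * d
    return forces, e_lj, e_coul
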