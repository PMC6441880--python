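"""Lennard-Jones + reaction-field Coulomb pair forces, per cutoff shell.

The nonbonded force on a site is split into a short-range part (charge
groups within R_s, evaluated every step) and a mid-range part (groups
between R_s and R_l, evaluated every n_m steps):

    f_i^nb = f_i^nb,s + f_i^nb,m

Electrostatics beyond R_l are represented by a homogeneous reaction
field: a pair potential

    V(r) = f q_i q_j [ 1/r + C_rf r^2 / (2 R_l^3) - (1 + C_rf/2)/R_l ],
    C_rf = 2 (eps_rf - 1) / (2 eps_rf + 1),

with the constant chosen so V(R_l) = 0 (the shift affects energies, not
forces).  Lennard-Jones uses the C6/C12 form without any truncation
smoothing; interactions beyond R_l are not calculated at all.

Cutoffs are group-based: once a molecule pair is on a shell list, *all*
its site-site interactions are computed, and intramolecular nonbonded
terms are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import SystemState
from .forcefield import ForceField
from .pairlist import TwinPairlist


@dataclass
class ForceReport:
    """Per-site forces (kJ mol^-1 nm^-1) and energies for one shell."""

    forces: np.ndarray          # (N, 3)
    e_lj: float                 # kJ/mol
    e_coul: float               # kJ/mol, Coulomb + reaction field
    virial: float               # sum over pairs of r_ij . f_ij, kJ/mol
    shell: str                  # short | mid | all

    @property
    def e_pot(self) -> float:
        return self.e_lj + self.e_coul


def lj_pair(r_vec: np.ndarray, c6: float, c12: float):
    """LJ force on site i (at +r_vec from j) and energy.

    V = C12/r^12 - C6/r^6; returns (force_on_i, energy).
    """
    r2 = float(np.dot(r_vec, r_vec))
    if r2 == 0.0:
        raise ValueError("zero separation in LJ pair")
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    e = c12 * inv6 * inv6 - c6 * inv6
    fmag = (12.0 * c12 * inv6 * inv6 - 6.0 * c6 * inv6) * inv2
    return fmag * np.asarray(r_vec, dtype=float), e


def rf_pair(r_vec: np.ndarray, q_i: float, q_j: float, eps_rf: float,
            r_long: float, fcoul: float = 138.935458):
    """Coulomb + reaction-field force on site i and energy.

    At eps_rf = 1 the RF constant vanishes and the interaction reduces
    to the bare (shifted) Coulomb form.
    """
    r2 = float(np.dot(r_vec, r_vec))
    if r2 == 0.0:
        raise ValueError("zero separation in RF pair")
    crf = 2.0 * (eps_rf - 1.0) / (2.0 * eps_rf + 1.0)
    r = np.sqrt(r2)
    qq = fcoul * q_i * q_j
    e = qq * (1.0 / r + crf * r2 / (2.0 * r_long**3)
              - (1.0 + crf / 2.0) / r_long)
    fmag = qq * (1.0 / (r2 * r) - crf / r_long**3)
    return fmag * np.asarray(r_vec, dtype=float), e


@njit(cache=True, fastmath=True)
def _shell_kernel(pos, box, pairs, first_site, nsites, type_idx, charge,
                  c6t, c12t, fcoul, crf, r_long, forces):
    """Accumulate LJ + RF forces over all site pairs of listed molecule
    pairs; returns (e_lj, e_coul, virial)."""
    e_lj = 0.0
    e_coul = 0.0
    virial = 0.0
    rl3 = r_long * r_long * r_long
    shift = (1.0 + crf / 2.0) / r_long
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    for p in range(pairs.shape[0]):
        m1 = pairs[p, 0]
        m2 = pairs[p, 1]
        f1 = first_site[m1]
        f2 = first_site[m2]
        for a in range(nsites[m1]):
            i = f1 + a
            for b in range(nsites[m2]):
                j = f2 + b
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.rint(dx * ibx)
                dy -= box[1] * np.rint(dy * iby)
                dz -= box[2] * np.rint(dz * ibz)
                r2 = dx * dx + dy * dy + dz * dz
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                ti = type_idx[i]
                tj = type_idx[j]
                c6 = c6t[ti, tj]
                c12 = c12t[ti, tj]
                e_lj += c12 * inv6 * inv6 - c6 * inv6
                fmag = (12.0 * c12 * inv6 * inv6 - 6.0 * c6 * inv6) * inv2
                qq = fcoul * charge[i] * charge[j]
                if qq != 0.0:
                    r = np.sqrt(r2)
                    e_coul += qq * (1.0 / r + crf * r2 / (2.0 * rl3) - shift)
                    fmag += qq * (1.0 / (r2 * r) - crf / rl3)
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                virial += dx * fx + dy * fy + dz * fz
    return e_lj, e_coul, virial


def shell_forces(state: SystemState, plist: TwinPairlist, shell: str,
                 ff: ForceField) -> ForceReport:
    """Sum LJ + RF over all site pairs of the molecule pairs in a shell.

    ``shell`` is ``"short"``, ``"mid"`` or ``"all"``; the ``"all"``
    result is computed as the elementwise sum of the two shells, so the
    force-splitting identity holds bitwise and single-range integration
    is bit-identical to a degenerate twin-range run.
    """
    if shell == "all":
        rs = shell_forces(state, plist, "short", ff)
        rm = shell_forces(state, plist, "mid", ff)
        return ForceReport(forces=rs.forces + rm.forces,
                           e_lj=rs.e_lj + rm.e_lj,
                           e_coul=rs.e_coul + rm.e_coul,
                           virial=rs.virial + rm.virial, shell="all")
    if shell == "short":
        pairs = plist.short_pairs
    elif shell == "mid":
        pairs = plist.mid_pairs
    else:
        raise ValueError(f"unknown shell {shell!r}")
    top = state.topology
    c6t, c12t, _ = ff.lj_tables()
    forces = np.zeros_like(state.positions)
    e_lj, e_coul, virial = _shell_kernel(
        state.positions, state.box, np.ascontiguousarray(pairs),
        top.first_site, top.sites_per_molecule, top.site_type_index,
        top.charges, c6t, c12t, ff.coulomb_constant, ff.crf, ff.r_long,
        forces)
    return ForceReport(forces=forces, e_lj=e_lj, e_coul=e_coul,
                       virial=virial, shell=shell)
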