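"""Leap-frog multiple-time-step integration with CFA/RESPA mid forces.

The discrete scheme advances half-step velocities and on-step positions:

    v(t + dt/2) = v(t - dt/2) + (f_s(t) + f_m_eff(t)) dt / m
    x(t + dt)   = x(t) + v(t + dt/2) dt

Short-range forces f_s are recomputed every step.  The mid-range shell
is refreshed every n_m steps and enters either as a constant force
(CFA: the cached vector is re-applied unchanged on every inner step) or
as an impulse (RESPA: n_m times the fresh force on refresh steps, zero
otherwise).  With n_m = 1 both reduce to plain single-list leap-frog.

Rigid bonds are enforced by SHAKE after every position update; the
centre-of-mass motion is removed periodically by the driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .constants import KB, PRESSURE_UNIT_BAR
from .core import (MTSConfig, SystemState, degrees_of_freedom,
                   validate_config)
from .forcefield import ForceField
from .nonbonded import shell_forces
from .pairlist import build_twin_pairlist, pairlist_change_fraction
from .thermostats import (ThermostatState, berendsen_barostat_scale,
                          nose_hoover_update, sd_velocity_update,
                          weak_coupling_scale)
from .trajectory import Trajectory


@dataclass
class MidForceCache:
    """Mid-shell forces frozen between outer-step refreshes."""

    forces: np.ndarray
    e_lj: float
    e_coul: float
    virial: float
    computed_at_step: int


def effective_mid_force(cache: MidForceCache, step: int, n_m: int,
                        application: str) -> np.ndarray:
    """Mid-range force entering the velocity update at this inner step."""
    if application == "CFA":
        return cache.forces
    if application == "RESPA":
        if step % n_m == 0:
            return n_m * cache.forces
        return np.zeros_like(cache.forces)
    raise ValueError(f"unknown application {application!r}")


def leapfrog_step(state: SystemState, short_force: np.ndarray,
                  mid_force_effective: np.ndarray, dt: float,
                  shake_tol: float = 1e-4) -> SystemState:
    """One unthermostatted leap-frog step (in place), then SHAKE."""
    f = short_force + mid_force_effective
    if not np.all(np.isfinite(f)):
        bad = int(np.argwhere(~np.isfinite(f))[0][0])
        raise FloatingPointError(f"non-finite force on site {bad}")
    m = state.topology.masses[:, None]
    state.velocities = state.velocities + (f / m) * dt
    _advance_positions(state, dt, shake_tol)
    return state


def _advance_positions(state: SystemState, dt: float,
                       shake_tol: float) -> np.ndarray:
    """Position update + SHAKE; returns the constraint displacement."""
    ref = state.positions
    trial = ref + state.velocities * dt
    top = state.topology
    if len(top.constraints):
        corrected, n_it = shake(ref, trial, top.constraints,
                                top.constraint_lengths,
                                1.0 / top.masses, tol=shake_tol)
        dx = corrected - trial
        state.velocities = state.velocities + dx / dt
        state.positions = corrected
    else:
        dx = np.zeros_like(trial)
        state.positions = trial
    state.time += dt
    state.step += 1
    return dx


@njit(cache=True)
def _shake_sweeps(ref, trial, ci, cj, d0sq, invm, tol, max_iter):
    n_con = ci.shape[0]
    for it in range(max_iter):
        done = True
        for k in range(n_con):
            i = ci[k]
            j = cj[k]
            rx = trial[i, 0] - trial[j, 0]
            ry = trial[i, 1] - trial[j, 1]
            rz = trial[i, 2] - trial[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            diff = r2 - d0sq[k]
            if abs(diff) > 2.0 * tol * d0sq[k]:
                done = False
                sx = ref[i, 0] - ref[j, 0]
                sy = ref[i, 1] - ref[j, 1]
                sz = ref[i, 2] - ref[j, 2]
                rs = rx * sx + ry * sy + rz * sz
                g = diff / (2.0 * rs * (invm[i] + invm[j]))
                trial[i, 0] -= g * invm[i] * sx
                trial[i, 1] -= g * invm[i] * sy
                trial[i, 2] -= g * invm[i] * sz
                trial[j, 0] += g * invm[j] * sx
                trial[j, 1] += g * invm[j] * sy
                trial[j, 2] += g * invm[j] * sz
        if done:
            return it
    return -1


def shake(positions_ref: np.ndarray, positions_trial: np.ndarray,
          constraints: np.ndarray, lengths: np.ndarray,
          inv_masses: np.ndarray, tol: float = 1e-4,
          max_iter: int = 1000) -> tuple[np.ndarray, int]:
    """Iterative constraint projection (Gauss-Seidel over constraints).

    Corrections are mass-weighted and directed along the *reference*
    bond vectors; convergence requires |d^2 - d0^2| / d0^2 <= 2 tol for
    every constraint.  Returns (corrected positions, sweeps used).
    """
    trial = np.array(positions_trial, dtype=float, copy=True)
    if len(constraints) == 0:
        return trial, 0
    n_it = _shake_sweeps(np.ascontiguousarray(positions_ref, dtype=float),
                         trial,
                         np.ascontiguousarray(constraints[:, 0]),
                         np.ascontiguousarray(constraints[:, 1]),
                         np.ascontiguousarray(lengths ** 2),
                         np.ascontiguousarray(inv_masses),
                         tol, max_iter)
    if n_it < 0:
        d = trial[constraints[:, 0]] - trial[constraints[:, 1]]
        resid = np.abs(np.sum(d * d, axis=1) - lengths**2) / lengths**2
        raise RuntimeError(f"SHAKE did not converge in {max_iter} sweeps; "
                           f"worst relative residual {resid.max():.3e}")
    return trial, n_it


def remove_com_motion(state: SystemState) -> SystemState:
    """Zero the total linear momentum (in place)."""
    m = state.topology.masses[:, None]
    p = np.sum(m * state.velocities, axis=0)
    state.velocities = state.velocities - p / np.sum(state.topology.masses)
    return state


def _bath_temperature(v: np.ndarray, mask: np.ndarray, masses: np.ndarray,
                      n_f: int) -> float:
    k = 0.5 * np.sum(masses[mask] * np.sum(v[mask] ** 2, axis=1))
    return 2.0 * k / (n_f * KB)


@dataclass
class SimulationResult:
    trajectory: Trajectory
    energy: pd.DataFrame
    final_state: SystemState
    pairlist_log: pd.DataFrame


def run_simulation(state: SystemState, ff: ForceField,
                   cfg: MTSConfig) -> SimulationResult:
    """Integrate ``cfg.n_steps`` inner steps and collect outputs.

    The loop per inner step t = s dt: rebuild the twin pairlist every
    n_p steps, compute short-shell forces every step (SR: the full list
    within R_l), refresh the mid cache every n_m steps, apply the
    CFA/RESPA effective mid force, couple the thermostat/barostat, take
    the leap-frog + SHAKE step and periodically stop the centre of mass.
    Deterministic for a given seed.
    """
    problems = validate_config(cfg, ff)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    problems = state.validate()
    if problems:
        raise ValueError("invalid state: " + "; ".join(problems))

    top = state.topology
    masses = top.masses
    rng = np.random.default_rng(cfg.seed)
    baths = list(top.species_names)
    nf = {b: degrees_of_freedom(top, b, com_removed=False) for b in baths}
    ts_state = {b: ThermostatState.for_bath(
        nf[b], cfg.t0_for(b), cfg.tau_t,
        cfg.chain_length if cfg.thermostat == "NHchain" else 1)
        for b in baths}
    bath_masks = {b: top.species_site_mask(b) for b in baths}

    com_stride = (max(1, round(cfg.com_removal_period / cfg.dt))
                  if cfg.com_removal_period > 0 else 0)
    energy_stride = max(1, round(cfg.energy_period / cfg.dt))
    traj_stride = max(1, round(cfg.traj_period / cfg.dt))

    traj = Trajectory(top)
    energy_rows: list[dict] = []
    plist_rows: list[dict] = []

    plist = None
    prev_plist = None
    mid_cache = MidForceCache(np.zeros_like(state.positions),
                              0.0, 0.0, 0.0, -1)
    sr = cfg.scheme == "SR"

    for s in range(cfg.n_steps):
        if s % cfg.n_p == 0:
            prev_plist, plist = plist, build_twin_pairlist(state, ff)
            row = {"step": state.step, "time": state.time,
                   "n_short": plist.n_short, "n_mid": plist.n_mid}
            # staleness diagnostic; pointless (and costly) when the
            # list is rebuilt every step
            if prev_plist is not None and cfg.n_p > 1:
                row["fraction_changed"] = pairlist_change_fraction(
                    prev_plist, plist).fraction_changed
            plist_rows.append(row)

        short = shell_forces(state, plist, "all" if sr else "short", ff)
        if sr:
            f_mid_eff = np.zeros_like(short.forces)
        else:
            if s % cfg.n_m == 0:
                rep = shell_forces(state, plist, "mid", ff)
                mid_cache = MidForceCache(rep.forces, rep.e_lj, rep.e_coul,
                                          rep.virial, s)
            f_mid_eff = effective_mid_force(mid_cache, s, cfg.n_m,
                                            cfg.application)
        f_total = short.forces + f_mid_eff
        if not np.all(np.isfinite(f_total)):
            bad = int(np.argwhere(~np.isfinite(f_total))[0][0])
            raise FloatingPointError(
                f"non-finite force on site {bad} at step {state.step}")

        record_energy = s % energy_stride == 0
        if record_energy:
            # potential terms at the pre-step configuration
            rec_step, rec_time = state.step, state.time
            if sr:
                e_lj, e_coul = short.e_lj, short.e_coul
            elif s % cfg.n_m == 0:
                e_lj = short.e_lj + mid_cache.e_lj
                e_coul = short.e_coul + mid_cache.e_coul
            else:
                rep = shell_forces(state, plist, "mid", ff)
                e_lj = short.e_lj + rep.e_lj
                e_coul = short.e_coul + rep.e_coul

        v_old = state.velocities
        kick = (f_total / masses[:, None]) * cfg.dt
        if cfg.thermostat == "none":
            v_new = v_old + kick
        elif cfg.thermostat == "WC":
            v_new = v_old + kick
            for b in baths:
                t_inst = _bath_temperature(v_new, bath_masks[b], masses,
                                           nf[b])
                lam = weak_coupling_scale(t_inst, cfg.t0_for(b), cfg.dt,
                                          cfg.tau_t)
                v_new[bath_masks[b]] *= lam
        elif cfg.thermostat in ("NH", "NHchain"):
            v_new = np.empty_like(v_old)
            for b in baths:
                mask = bath_masks[b]
                k_inst = 0.5 * np.sum(masses[mask]
                                      * np.sum(v_old[mask] ** 2, axis=1))
                scale = nose_hoover_update(ts_state[b], k_inst, nf[b],
                                           cfg.t0_for(b), cfg.dt)
                v_new[mask] = v_old[mask] * scale + kick[mask]
        elif cfg.thermostat == "SD":
            v_new = np.empty_like(v_old)
            for b in baths:
                mask = bath_masks[b]
                v_new[mask] = sd_velocity_update(
                    v_old[mask], f_total[mask], masses[mask], cfg.dt,
                    cfg.gamma, cfg.t0_for(b), rng)
        else:  # pragma: no cover - caught by validate_config
            raise ValueError(cfg.thermostat)

        state.velocities = v_new
        dx_con = _advance_positions(state, cfg.dt, shake_tol=1e-4)

        if cfg.barostat == "berendsen-xy":
            vol = float(np.prod(state.box))
            k_tot = 0.5 * np.sum(masses[:, None] * state.velocities**2)
            vir = short.virial + (0.0 if sr else mid_cache.virial)
            vir_con = float(np.sum(state.positions * masses[:, None]
                                   * dx_con) / cfg.dt**2)
            p_inst = (2.0 * k_tot + vir + vir_con) / (3.0 * vol) \
                * PRESSURE_UNIT_BAR
            mu = berendsen_barostat_scale(p_inst, cfg.p0, cfg.dt, cfg.tau_b,
                                          cfg.kappa)
            state.box[:2] *= mu
            state.positions[:, :2] *= mu

        if com_stride and (s + 1) % com_stride == 0:
            remove_com_motion(state)

        if record_energy:
            v_mid = 0.5 * (v_old + state.velocities)
            e_kin = float(0.5 * np.sum(masses[:, None] * v_mid**2))
            row = {"step": rec_step, "time": rec_time,
                   "e_lj": e_lj, "e_coul": e_coul, "e_pot": e_lj + e_coul,
                   "e_kin": e_kin, "e_tot": e_kin + e_lj + e_coul}
            for b in baths:
                mask = bath_masks[b]
                kb_half = 0.5 * np.sum(masses[mask]
                                       * np.sum(state.velocities[mask]**2,
                                                axis=1))
                row[f"KE_{b}"] = kb_half
                row[f"T_{b}"] = 2.0 * kb_half / (nf[b] * KB)
            energy_rows.append(row)

        if (s + 1) % traj_stride == 0:
            traj.append(state.time, state.positions, state.box)

    return SimulationResult(trajectory=traj,
                            energy=pd.DataFrame(energy_rows),
                            final_state=state,
                            pairlist_log=pd.DataFrame(plist_rows))
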