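"""Temperature coupling (WC, NH, NHchain, SD) and the Berendsen barostat.

Each solvent species is its own temperature bath: a bath's scaling uses
only that bath's kinetic energy and degrees of freedom.  The
deterministic thermostats act as a uniform per-bath velocity scale on the
leap-frog half-step velocities and therefore conserve the bath's linear
momentum; stochastic dynamics perturbs every degree of freedom
independently and does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB


@dataclass
class ThermostatState:
    """Per-bath Nose-Hoover chain variables xi_k (ps^-1) and masses Q_k.

    Q_1 = N_f k_B T0 tau^2 and Q_k = k_B T0 tau^2 for k > 1; weak
    coupling holds no state and stochastic dynamics only the RNG.
    """

    xi: np.ndarray = field(default_factory=lambda: np.zeros(1))
    q: np.ndarray = field(default_factory=lambda: np.ones(1))

    @classmethod
    def for_bath(cls, n_f: int, t0: float, tau: float,
                 chain_length: int = 1) -> "ThermostatState":
        q = np.full(chain_length, KB * t0 * tau**2)
        q[0] *= n_f
        return cls(xi=np.zeros(chain_length), q=q)


def weak_coupling_scale(t_inst: float, t0: float, dt: float,
                        tau: float) -> float:
    """Berendsen velocity-scaling factor lambda = sqrt(1 + (dt/tau)(T0/T - 1)).

    A negative radicand (possible for tiny baths far above target) floors
    the factor at 0.8 rather than aborting the run.
    """
    if t_inst <= 0:
        raise ValueError(f"instantaneous temperature must be > 0, "
                         f"got {t_inst}")
    rad = 1.0 + (dt / tau) * (t0 / t_inst - 1.0)
    if rad < 0.64:
        return 0.8
    return float(np.sqrt(rad))


def nose_hoover_update(ts: ThermostatState, k_inst: float, n_f: int,
                       t0: float, dt: float) -> float:
    """Advance the NH(-chain) friction variables; return the velocity scale.

    Single-variable NH:  dxi/dt = (2K - N_f k_B T0)/Q_1; the chain adds
    the standard coupling of each xi_k to the fluctuations of xi_{k-1}.
    Velocities are then scaled by (1 - xi_1 dt).
    """
    xi, q = ts.xi, ts.q
    m = len(xi)
    gk = np.empty(m)
    gk[0] = (2.0 * k_inst - n_f * KB * t0) / q[0]
    for k in range(1, m):
        gk[k] = (q[k - 1] * xi[k - 1] ** 2 - KB * t0) / q[k]
    # integrate last-to-first so each xi_k feels the pre-update xi_{k+1}
    for k in range(m - 1, -1, -1):
        if k < m - 1:
            xi[k] += dt * (gk[k] - xi[k] * xi[k + 1])
        else:
            xi[k] += dt * gk[k]
    return float(1.0 - xi[0] * dt)


def sd_velocity_update(v: np.ndarray, f: np.ndarray, masses: np.ndarray,
                       dt: float, gamma: float, t0: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Langevin leap-frog velocity update with exact OU friction.

    v' = c1 v + (f/m) dt_eff + sigma xi, with c1 = exp(-gamma dt),
    dt_eff = (1 - c1)/gamma (-> dt as gamma -> 0) and
    sigma^2 = (k_B T0/m)(1 - c1^2); the free-particle stationary
    distribution is exactly Maxwell-Boltzmann at T0, and gamma = 0
    reduces the update to the deterministic leap-frog kick.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    m = masses[:, None]
    if gamma == 0.0:
        return v + (f / m) * dt
    c1 = np.exp(-gamma * dt)
    dt_eff = (1.0 - c1) / gamma
    sigma = np.sqrt(KB * t0 / m * (1.0 - c1 * c1))
    noise = rng.standard_normal(v.shape)
    return c1 * v + (f / m) * dt_eff + sigma * noise


def berendsen_barostat_scale(p_inst: float, p0: float, dt: float,
                             tau_b: float, kappa: float = 4.5e-5) -> float:
    """Semi-anisotropic (x/y) Berendsen box-scaling factor.

    mu_xy = [1 - kappa (dt/tau_b)(P0 - P_inst)]^(1/2) is applied to the
    x and y box edges and coordinates while z stays fixed; the factor is
    clamped to [0.95, 1.05] against pressure spikes.
    """
    mu2 = 1.0 - kappa * (dt / tau_b) * (p0 - p_inst)
    mu = float(np.sqrt(max(mu2, 0.0)))
    return min(max(mu, 0.95), 1.05)
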