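"""Scheme x thermostat x outer-step comparisons and the artefact statistic.

The central quantity is the *interfacial excess*: the peak of the
running-averaged apolar density difference (test minus single-range
reference) inside a window around the polar/apolar interface,
normalized by the reference apolar plateau density.  A positive excess
means the integrator piled up apolar material at the interface — the
multiple-time-step resonance artefact under study.  Uncertainty comes
from a moving-block bootstrap over trajectory frames, which respects
the time correlation of the density field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (DensityProfile, planar_density_profile,
                       running_average)
from .builder import SystemSpec, build_system
from .core import MTSConfig, SystemState
from .forcefield import ForceField, default_forcefield
from .integrator import SimulationResult, run_simulation
from .trajectory import Trajectory


@dataclass
class GridCell:
    """One integration setup: scheme, mid-force application, thermostat.

    ``n`` is the outer period in inner steps: n_m = n_p for TR cells and
    the pairlist period n_p for SR cells (whose n_m is 1 by definition).
    """

    scheme: str                 # SR | TR
    application: str = "CFA"    # CFA | RESPA (TR only)
    n: int = 1
    thermostat: str = "NH"

    @property
    def name(self) -> str:
        if self.scheme == "SR":
            return f"SR_{self.thermostat}_np{self.n}"
        return f"TR_{self.application}_{self.thermostat}_nm{self.n}"

    def config(self, base: MTSConfig) -> MTSConfig:
        if self.scheme == "SR":
            return replace(base, scheme="SR", n_m=1, n_p=self.n,
                           thermostat=self.thermostat)
        return replace(base, scheme="TR", application=self.application,
                       n_m=self.n, n_p=self.n, thermostat=self.thermostat)


@dataclass
class ExperimentGrid:
    """A set of cells sharing one system, horizon, and seed list."""

    cells: list[GridCell]
    system: SystemSpec
    seeds: tuple[int, ...] = (1, 2, 3)
    production: float = 50.0        # ps
    equilibration: float = 10.0     # ps
    t0: float = 300.0               # K
    dt: float = 0.002               # ps
    r_short: float = 0.6            # nm (desk-scale cutoffs)
    r_long: float = 1.0


def desk_system(seed: int = 0) -> SystemSpec:
    """Default desk-scale planar layer: 200 polar + 60 apolar molecules."""
    return SystemSpec(geometry="layer", n_polar=200, n_apolar=60,
                      box=(2.2, 2.2, 6.6), t_init=300.0, seed=seed)


def desk_grid(seeds: tuple[int, ...] = (1, 2, 3),
              production: float = 50.0) -> ExperimentGrid:
    """The default comparison grid mirroring the headline experiment."""
    cells = [
        GridCell("SR", n=1, thermostat="NH"),
        GridCell("SR", n=20, thermostat="NH"),
        GridCell("TR", "CFA", 5, "NH"),
        GridCell("TR", "CFA", 10, "NH"),
        GridCell("TR", "CFA", 20, "NH"),
        GridCell("TR", "RESPA", 10, "NH"),
        GridCell("TR", "RESPA", 20, "NH"),
        # stochastic-dynamics pair: its own SR reference, because the
        # thermostat itself changes the interface structure slightly
        GridCell("SR", n=1, thermostat="SD"),
        GridCell("TR", "CFA", 10, "SD"),
    ]
    return ExperimentGrid(cells=cells, system=desk_system(),
                          seeds=seeds, production=production)


def grid_forcefield(grid: ExperimentGrid) -> ForceField:
    return default_forcefield(r_short=grid.r_short, r_long=grid.r_long)


def equilibrate(state: SystemState, ff: ForceField, t_sim: float = 10.0,
                t0: float = 300.0, dt: float = 0.002,
                seed: int = 0) -> SystemState:
    """Short single-range weak-coupling run to relax a built system."""
    cfg = MTSConfig(dt=dt, n_steps=round(t_sim / dt), scheme="SR",
                    n_m=1, n_p=1, thermostat="WC", t0=t0, seed=seed,
                    traj_period=t_sim, energy_period=t_sim)
    return run_simulation(state, ff, cfg).final_state


def prepare_initial_states(grid: ExperimentGrid,
                           ff: ForceField | None = None
                           ) -> dict[int, SystemState]:
    """Build + equilibrate one shared starting state per seed.

    All cells of the grid start production from the same coordinates
    for a given seed, so cell differences are purely due to the
    integration setup.
    """
    ff = ff or grid_forcefield(grid)
    out = {}
    for seed in grid.seeds:
        state = build_system(replace(grid.system, seed=seed), ff)
        out[seed] = equilibrate(state, ff, grid.equilibration, grid.t0,
                                grid.dt, seed=seed)
    return out


@dataclass
class CellRun:
    cell: GridCell
    seed: int
    result: SimulationResult | None
    profile: DensityProfile | None
    error: str | None = None


@dataclass
class GridResult:
    grid: ExperimentGrid
    runs: dict[tuple[str, int], CellRun] = field(default_factory=dict)

    def run(self, cell_name: str, seed: int) -> CellRun:
        return self.runs[(cell_name, seed)]

    def cell_names(self) -> list[str]:
        return [c.name for c in self.grid.cells]


def run_grid(grid: ExperimentGrid, ff: ForceField | None = None,
             initial_states: dict[int, SystemState] | None = None,
             n_bins: int = 100, recenter: str | None = "C",
             progress=None) -> GridResult:
    """Run every (cell, seed) production and collect density profiles.

    Cells are independent given the shared starting states, so the
    result is identical regardless of execution order; per-cell failures
    are isolated into the corresponding :class:`CellRun`.
    """
    ff = ff or grid_forcefield(grid)
    starts = initial_states or prepare_initial_states(grid, ff)
    out = GridResult(grid=grid)
    n_steps = round(grid.production / grid.dt)
    base = MTSConfig(dt=grid.dt, n_steps=n_steps, t0=grid.t0)
    for cell in grid.cells:
        for seed in grid.seeds:
            cfg = replace(cell.config(base), seed=seed)
            if progress:
                progress(cell.name, seed)
            try:
                result = run_simulation(starts[seed].copy(), ff, cfg)
                profile = planar_density_profile(result.trajectory, n_bins,
                                                 recenter=recenter)
                out.runs[(cell.name, seed)] = CellRun(
                    cell, seed, result, profile)
            except Exception as exc:   # isolate per-cell failures
                out.runs[(cell.name, seed)] = CellRun(
                    cell, seed, None, None, error=f"{type(exc).__name__}: "
                    f"{exc}")
    return out


def locate_interface(ref: DensityProfile, apolar: str = "C",
                     polar: str = "W", window: int = 7
                     ) -> tuple[float, float]:
    """Interface position and apolar plateau density from a reference.

    The plateau is the mean smoothed apolar density over bins at >= 80%
    of its maximum; the interface is the z where the smoothed apolar
    density crosses half the plateau on the side facing the polar slab.
    Raises if the phases are mixed (no plateau or no crossing).
    """
    z = ref.bin_centers
    s_ap = running_average(ref.density[apolar], window)
    s_po = running_average(ref.density[polar], window)
    peak = float(np.max(s_ap))
    if peak <= 0:
        raise ValueError("no apolar phase found in the reference profile")
    plateau = float(np.mean(s_ap[s_ap >= 0.8 * peak]))
    half = 0.5 * plateau
    # polar slab position = density-weighted mean z of the polar species
    if np.sum(s_po) <= 0:
        raise ValueError("no polar phase found in the reference profile")
    z_polar = float(np.sum(z * s_po) / np.sum(s_po))
    crossings = []
    for i in range(len(z) - 1):
        a, b = s_ap[i] - half, s_ap[i + 1] - half
        if a == b:
            continue
        if a * b <= 0 and (a != 0 or b != 0):
            frac = a / (a - b)
            crossings.append(z[i] + frac * (z[i + 1] - z[i]))
    if not crossings:
        raise ValueError("no interface detectable: apolar density never "
                         "crosses half its plateau (mixed system?)")
    z_int = min(crossings, key=lambda c: abs(c - z_polar))
    return float(z_int), plateau


def interfacial_excess(profile: DensityProfile, ref: DensityProfile,
                       interface_window: float = 0.5, apolar: str = "C",
                       polar: str = "W", window: int = 7) -> float:
    """Plateau-normalized peak apolar density excess at the interface.

    statistic = max_{|z - z_int| <= w} <rho_apolar - rho_apolar,ref>_7
                / rho_plateau,ref
    """
    if (len(profile.bin_edges) != len(ref.bin_edges)
            or not np.allclose(profile.bin_edges, ref.bin_edges)):
        raise ValueError("profile and reference have mismatched binning")
    z_int, plateau = locate_interface(ref, apolar, polar, window)
    z = ref.bin_centers
    delta = running_average(profile.density[apolar] - ref.density[apolar],
                            window)
    sel = np.abs(z - z_int) <= interface_window
    if not np.any(sel):
        raise ValueError("interface window contains no bins")
    return float(np.max(delta[sel]) / plateau)


def interfacial_excess_bootstrap(traj: Trajectory, ref: DensityProfile,
                                 interface_window: float = 0.5,
                                 apolar: str = "C", polar: str = "W",
                                 n_bins: int = 100, window: int = 7,
                                 block: float = 5.0, n_boot: int = 200,
                                 alpha: float = 0.05, seed: int = 0,
                                 recenter: str | None = "C"
                                 ) -> tuple[float, float, float]:
    """Statistic with a moving-block bootstrap CI over frames.

    Frames are resampled in contiguous blocks of ``block`` ps to respect
    autocorrelation; returns (statistic, ci_low, ci_high) at confidence
    1 - alpha (equal-tailed percentile interval).
    """
    prof = planar_density_profile(traj, n_bins, recenter=recenter)
    stat = interfacial_excess(prof, ref, interface_window, apolar, polar,
                              window)
    period = traj.frame_period()
    n_frames = traj.n_frames
    frames_per_block = max(1, round(block / period))
    n_blocks = max(1, int(np.ceil(n_frames / frames_per_block)))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, max(1, n_frames - frames_per_block + 1),
                              size=n_blocks)
        idx = np.concatenate([np.arange(s, s + frames_per_block)
                              for s in starts])[:n_frames]
        sub = traj.subset(idx)
        p = planar_density_profile(sub, n_bins, recenter=recenter)
        stats[b] = interfacial_excess(p, ref, interface_window, apolar,
                                      polar, window)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return stat, float(lo), float(hi)


def null_excess_quantile(ref_traj: Trajectory, ref: DensityProfile,
                         q: float = 0.95, interface_window: float = 0.5,
                         apolar: str = "C", polar: str = "W",
                         n_bins: int = 100, window: int = 7,
                         block: float = 5.0, n_null: int = 200,
                         seed: int = 0,
                         recenter: str | None = "C") -> float:
    """Noise quantile of the excess statistic under the no-artefact null.

    The max-based excess statistic is positively biased: even two runs
    with identical physics differ by sampling noise, so its null
    distribution sits above zero.  This estimates that distribution by
    splitting the *reference* run into random balanced halves (block
    granularity ``block`` ps) and computing the statistic between the
    half-profiles.  Each half carries twice the variance of the full
    profile, so the half-difference overestimates the test-vs-reference
    noise by sqrt(2); the statistic is rescaled accordingly.  A cell's
    excess is significant when it exceeds this quantile.
    """
    z_int, plateau = locate_interface(ref, apolar, polar, window)
    z = ref.bin_centers
    sel = np.abs(z - z_int) <= interface_window
    period = ref_traj.frame_period()
    fpb = max(1, round(block / period))
    n_frames = ref_traj.n_frames
    n_blocks = n_frames // fpb
    if n_blocks < 4:
        raise ValueError("too few blocks for the null split; reduce the "
                         "block length or lengthen the run")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_null)
    for b in range(n_null):
        order = rng.permutation(n_blocks)
        half = n_blocks // 2
        ia = np.concatenate([np.arange(k * fpb, (k + 1) * fpb)
                             for k in order[:half]])
        ib = np.concatenate([np.arange(k * fpb, (k + 1) * fpb)
                             for k in order[half:2 * half]])
        pa = planar_density_profile(ref_traj.subset(ia), n_bins,
                                    recenter=recenter)
        pb = planar_density_profile(ref_traj.subset(ib), n_bins,
                                    recenter=recenter)
        delta = running_average(pa.density[apolar] - pb.density[apolar],
                                window) / np.sqrt(2.0)
        stats[b] = np.max(delta[sel]) / plateau
    return float(np.quantile(stats, q))


def artefact_summary(res: GridResult, ref_cell: str,
                     interface_window: float = 0.5, n_bins: int = 100,
                     block: float = 5.0, n_boot: int = 200,
                     alpha: float = 0.05,
                     recenter: str | None = "C",
                     cells: list[str] | None = None) -> pd.DataFrame:
    """Interfacial-excess statistic per (cell, seed) with uncertainty.

    Each seed's reference profile comes from the same-seed run of
    ``ref_cell`` (shared starting coordinates); the reference cell
    itself reports statistic 0 by construction.  Columns: the statistic,
    a descriptive block-bootstrap CI over the test run's frames, the
    95% null-noise quantile from the reference split
    (:func:`null_excess_quantile`), and the per-seed one-sided verdict
    ``significant`` = statistic > null quantile.  ``cells`` restricts
    the summary to a subset of cell names (e.g. to compare the cells of
    one thermostat against their own-thermostat reference).
    """
    rows = []
    grid = res.grid
    wanted = [c for c in grid.cells
              if cells is None or c.name in cells]
    for seed in grid.seeds:
        ref_run = res.run(ref_cell, seed)
        if ref_run.error:
            raise RuntimeError(f"reference cell failed for seed {seed}: "
                               f"{ref_run.error}")
        ref_prof = ref_run.profile
        null_q = null_excess_quantile(
            ref_run.result.trajectory, ref_prof, q=1.0 - alpha,
            interface_window=interface_window, n_bins=n_bins,
            block=block, n_null=n_boot, seed=seed, recenter=recenter)
        for cell in wanted:
            run = res.run(cell.name, seed)
            if run.error:
                rows.append({"cell": cell.name, "seed": seed,
                             "n_outer_fs": cell.n * grid.dt * 1e3,
                             "statistic": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "null_q95": null_q,
                             "significant": False, "error": run.error})
                continue
            stat, lo, hi = interfacial_excess_bootstrap(
                run.result.trajectory, ref_prof, interface_window,
                n_bins=n_bins, block=block, n_boot=n_boot, alpha=alpha,
                seed=seed, recenter=recenter)
            rows.append({"cell": cell.name, "seed": seed,
                         "n_outer_fs": cell.n * grid.dt * 1e3,
                         "statistic": stat, "ci_low": lo, "ci_high": hi,
                         "null_q95": null_q,
                         "significant": bool(stat > null_q),
                         "error": None})
    return pd.DataFrame(rows)


def cell_significance(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-cell aggregation over seeds: a cell shows a significant
    positive excess when the majority of its seeds exceed their
    null-noise quantile."""
    out = []
    for cell, sub in summary.groupby("cell", sort=False):
        ok = sub["error"].isna() if "error" in sub else np.ones(len(sub),
                                                                bool)
        sub = sub[ok]
        sig = int(sub["significant"].sum())
        out.append({"cell": cell,
                    "n_seeds": len(sub),
                    "mean_statistic": sub["statistic"].mean(),
                    "n_significant": sig,
                    "significant": bool(sig > len(sub) / 2)})
    return pd.DataFrame(out)
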