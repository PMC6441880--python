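"""Charge-group twin pairlists and pairlist-change statistics.

Each solvent molecule is one neutral charge group; shell membership is
decided by the minimum-image distance between molecular centers of
geometry (unweighted site mean).  Two lists are kept: the short shell
(r <= R_s, forces every step) and the mid shell (R_s < r <= R_l, forces
every n_m steps).  Boundary ties: a distance exactly R_s is short,
exactly R_l is mid.  No Verlet skin is added — lists are exact at build
time and simply reused until the next rebuild, which is precisely the
approximation whose consequences this package studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import SystemState
from .forcefield import ForceField


@dataclass
class TwinPairlist:
    short_pairs: np.ndarray     # (Ns, 2) molecule-index pairs, i < j
    mid_pairs: np.ndarray       # (Nm, 2)
    built_at_step: int

    @property
    def n_short(self) -> int:
        return len(self.short_pairs)

    @property
    def n_mid(self) -> int:
        return len(self.mid_pairs)

    def all_pairs(self) -> np.ndarray:
        """Union of both shells (the effective single-range list)."""
        return np.concatenate([self.short_pairs, self.mid_pairs], axis=0)


@dataclass
class PairlistChangeStats:
    n_added: int
    n_removed: int
    n_reference: int

    @property
    def fraction_changed(self) -> float:
        if self.n_reference == 0:
            raise ValueError("reference pairlist is empty")
        return (self.n_added + self.n_removed) / self.n_reference


def molecule_centers(state: SystemState) -> np.ndarray:
    """Per-molecule center of geometry (unweighted site mean), (M, 3)."""
    top = state.topology
    counts = top.sites_per_molecule.astype(float)
    sums = np.stack([np.bincount(top.site_molecule,
                                 weights=state.positions[:, d],
                                 minlength=top.n_molecules)
                     for d in range(3)], axis=1)
    return sums / counts[:, None]


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box * np.rint(d / box)


def build_twin_pairlist(state: SystemState, ff: ForceField) -> TwinPairlist:
    """Exhaustive twin pairlist over molecule (charge-group) centers.

    Raises if the outer cutoff violates the minimum-image requirement
    R_l < min(box)/2.
    """
    box = state.box
    if ff.r_long >= float(np.min(box)) / 2.0:
        raise ValueError(
            f"outer cutoff R_l={ff.r_long} nm must be < half the smallest "
            f"box edge ({float(np.min(box)) / 2.0:.3f} nm)")
    centers = molecule_centers(state)
    short_pairs, mid_pairs = _classify_pairs(
        np.ascontiguousarray(centers), np.ascontiguousarray(box, float),
        ff.r_short**2, ff.r_long**2)
    return TwinPairlist(short_pairs, mid_pairs, built_at_step=state.step)


@njit(cache=True, fastmath=True)
def _classify_pairs(centers, box, rs2, rl2):
    m = centers.shape[0]
    max_pairs = m * (m - 1) // 2
    short = np.empty((max_pairs, 2), dtype=np.int64)
    mid = np.empty((max_pairs, 2), dtype=np.int64)
    ns = 0
    nm = 0
    for i in range(m):
        for j in range(i + 1, m):
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 <= rs2:
                short[ns, 0] = i
                short[ns, 1] = j
                ns += 1
            elif r2 <= rl2:
                mid[nm, 0] = i
                mid[nm, 1] = j
                nm += 1
    return short[:ns].copy(), mid[:nm].copy()


def _encode(pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.empty(0, dtype=np.int64)
    return pairs[:, 0].astype(np.int64) << 32 | pairs[:, 1].astype(np.int64)


def pairlist_change_fraction(a: TwinPairlist, b: TwinPairlist,
                             per_shell: bool = False):
    """Symmetric-difference statistics between two builds.

    By default the union of both shells is compared (membership within
    R_l); with ``per_shell=True`` a dict with ``union``, ``short`` and
    ``mid`` statistics is returned, since a pair migrating between shells
    counts as a change for the shells but not for the union.
    """
    def stats(pa: np.ndarray, pb: np.ndarray) -> PairlistChangeStats:
        ka, kb = _encode(pa), _encode(pb)
        n_common = len(np.intersect1d(ka, kb, assume_unique=True))
        return PairlistChangeStats(n_added=len(kb) - n_common,
                                   n_removed=len(ka) - n_common,
                                   n_reference=len(ka))

    union = stats(a.all_pairs(), b.all_pairs())
    if not per_shell:
        return union
    return {"union": union,
            "short": stats(a.short_pairs, b.short_pairs),
            "mid": stats(a.mid_pairs, b.mid_pairs)}


def dump_pairlist_stats(rows: list[dict], path) -> None:
    """Write per-build pairlist sizes/change fractions as a text table."""
    import pandas as pd
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
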