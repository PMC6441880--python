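"""Force-field containers and the two built-in solvent presets.

The force field is deliberately small: per-species site masses, charges,
Lennard-Jones types, a rigid local geometry with distance constraints, the
twin cutoffs ``r_short``/``r_long`` and the reaction-field permittivity.
Two presets are provided:

* ``"W"`` — a rigid three-site polar solvent (SPC-like geometry: one
  negative oxygen-like site carrying the LJ sphere, two positive
  hydrogen-like sites, rigid triangle via three distance constraints).
* ``"C"`` — a single-site neutral apolar Lennard-Jones solvent with the
  mass and size of a chloroform-like molecule.

The cross LJ attraction between the two species is scaled down so the
liquids demix at 300 K; the density artefact under study is a property of
the integrator, not of the specific chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import FCOUL


@dataclass
class Species:
    """Definition of one molecular species (one neutral charge group)."""

    name: str
    site_names: list[str]
    masses: np.ndarray          # u, shape (n_sites,)
    charges: np.ndarray         # e, shape (n_sites,)
    site_types: list[str]       # LJ type name per site
    geometry: np.ndarray        # nm, shape (n_sites, 3), centered on the COG
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    init_density: float = 10.0  # molecules/nm^3 used by the system builder

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def net_charge(self) -> float:
        return float(np.sum(self.charges))

    @property
    def mol_mass(self) -> float:
        return float(np.sum(self.masses))


@dataclass
class ForceField:
    """Nonbonded parameters plus the twin cutoffs and RF permittivity.

    ``lj_types`` maps an LJ type name to its self-interaction (C6, C12) in
    kJ mol^-1 nm^6 / kJ mol^-1 nm^12.  Unlike pairs combine by geometric
    mean unless an explicit entry exists in ``pair_overrides`` (keyed by a
    sorted type-name tuple), which acts as the explicit pair table.
    """

    species: dict[str, Species]
    lj_types: dict[str, tuple[float, float]]
    r_short: float = 0.8        # nm, inner cutoff R_s
    r_long: float = 1.4         # nm, outer cutoff R_l
    eps_rf: float = 78.5        # RF continuum permittivity
    coulomb_constant: float = FCOUL
    pair_overrides: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    @property
    def crf(self) -> float:
        """Reaction-field constant 2(eps-1)/(2 eps + 1)."""
        e = self.eps_rf
        return 2.0 * (e - 1.0) / (2.0 * e + 1.0)

    def lj_pair_params(self, type_a: str, type_b: str) -> tuple[float, float]:
        key = tuple(sorted((type_a, type_b)))
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        c6a, c12a = self.lj_types[type_a]
        c6b, c12b = self.lj_types[type_b]
        return (np.sqrt(c6a * c6b), np.sqrt(c12a * c12b))

    def type_names(self) -> list[str]:
        return sorted(self.lj_types)

    def lj_tables(self) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
        """Dense symmetric (C6, C12) tables over all LJ types.

        The tables are cached; call :meth:`clear_cache` after mutating
        ``lj_types`` or ``pair_overrides``.
        """
        cached = getattr(self, "_lj_tables_cache", None)
        if cached is not None:
            return cached
        names = self.type_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        c6 = np.zeros((n, n))
        c12 = np.zeros((n, n))
        for a in names:
            for b in names:
                c6[index[a], index[b]], c12[index[a], index[b]] = \
                    self.lj_pair_params(a, b)
        self._lj_tables_cache = (c6, c12, index)
        return self._lj_tables_cache

    def clear_cache(self) -> None:
        self._lj_tables_cache = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        out: list[str] = []
        if not (0.0 < self.r_short <= self.r_long):
            out.append(f"cutoffs must satisfy 0 < R_s <= R_l, got "
                       f"R_s={self.r_short}, R_l={self.r_long}")
        if self.eps_rf < 1.0:
            out.append(f"eps_rf must be >= 1, got {self.eps_rf}")
        for name, sp in self.species.items():
            if np.any(sp.masses <= 0):
                out.append(f"species {name}: all masses must be > 0")
            if abs(sp.net_charge) > 1e-9:
                out.append(f"species {name}: net charge "
                           f"{sp.net_charge:g} != 0 (one neutral charge group)")
        for c6, c12 in self.lj_types.values():
            if c12 < 0:
                out.append("LJ C12 must be >= 0")
        return out


def _lj_from_sigma_eps(sigma: float, eps: float) -> tuple[float, float]:
    return 4.0 * eps * sigma**6, 4.0 * eps * sigma**12


def spc_like_water() -> Species:
    """Rigid 3-site polar solvent: O-H 0.1 nm, H-O-H 109.47 deg."""
    d_oh = 0.1
    theta = np.deg2rad(109.47)
    d_hh = 2.0 * d_oh * np.sin(theta / 2.0)
    # place in the x-y plane, O on the symmetry axis
    h_y = d_hh / 2.0
    h_x = d_oh * np.cos(theta / 2.0)
    geom = np.array([
        [0.0, 0.0, 0.0],
        [h_x, +h_y, 0.0],
        [h_x, -h_y, 0.0],
    ])
    geom -= geom.mean(axis=0)
    return Species(
        name="W",
        site_names=["OW", "HW1", "HW2"],
        masses=np.array([15.9994, 1.008, 1.008]),
        charges=np.array([-0.82, 0.41, 0.41]),
        site_types=["OW", "H", "H"],
        geometry=geom,
        constraints=[(0, 1, d_oh), (0, 2, d_oh), (1, 2, d_hh)],
        init_density=12.5,
    )


def apolar_lj() -> Species:
    """Single-site neutral apolar solvent (chloroform-like mass and size)."""
    return Species(
        name="C",
        site_names=["C"],
        masses=np.array([119.38]),
        charges=np.array([0.0]),
        site_types=["CL"],
        geometry=np.zeros((1, 3)),
        constraints=[],
        init_density=14.5,
    )


def default_forcefield(r_short: float = 0.8, r_long: float = 1.4,
                       eps_rf: float = 78.5,
                       cross_scale: float = 0.6) -> ForceField:
    """Two-species demixing force field (polar W + apolar C).

    ``cross_scale`` multiplies the geometric-mean W-C attraction and
    repulsion, weakening the cross interaction enough that the liquids
    phase-separate at 300 K.
    """
    # SPC oxygen LJ parameters (GROMOS units)
    c6_ow, c12_ow = 2.617346e-3, 2.634129e-6
    # sigma 0.47 nm; eps 3.0 kJ/mol keeps the LJ liquid well below its
    # critical temperature at 300 K
    c6_cl, c12_cl = _lj_from_sigma_eps(0.47, 3.0)
    ff = ForceField(
        species={"W": spc_like_water(), "C": apolar_lj()},
        lj_types={"OW": (c6_ow, c12_ow), "H": (0.0, 0.0),
                  "CL": (c6_cl, c12_cl)},
        r_short=r_short, r_long=r_long, eps_rf=eps_rf,
    )
    c6x = cross_scale * np.sqrt(c6_ow * c6_cl)
    c12x = cross_scale * np.sqrt(c12_ow * c12_cl)
    ff.pair_overrides[("CL", "OW")] = (c6x, c12x)
    return ff
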