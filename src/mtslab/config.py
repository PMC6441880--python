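"""YAML run-configuration loading.

One document per run, three optional sections with defaults equal to
the standard protocol values (inner step 2 fs, cutoffs 0.8/1.4 nm,
eps_rf 78.5, tau_T 0.1 ps, gamma 10 ps^-1, chain length 3, COM removal
every 1 ps):

    system:      {geometry, n_polar, n_apolar, box, droplet_radius,
                  t_init, seed}
    forcefield:  {r_short, r_long, eps_rf, cross_scale}
    run:         any MTSConfig field (dt, n_steps, scheme, application,
                  n_m, n_p, thermostat, tau_t, chain_length, gamma, t0,
                  barostat, tau_b, p0, kappa, com_removal_period, seed,
                  traj_period, energy_period)
    equilibration: {time}   # ps of single-range pre-run, default 10
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .builder import SystemSpec
from .core import MTSConfig
from .forcefield import ForceField, default_forcefield


def load_config(path) -> tuple[SystemSpec, ForceField, MTSConfig, float]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    sys_doc = dict(doc.get("system", {}))
    sys_doc.setdefault("geometry", "layer")
    sys_doc.setdefault("n_polar", 200)
    sys_doc.setdefault("n_apolar", 60)
    sys_doc.setdefault("box", [2.2, 2.2, 6.6])
    sys_doc["box"] = tuple(float(v) for v in sys_doc["box"])
    spec = SystemSpec(**sys_doc)

    ff_doc = dict(doc.get("forcefield", {}))
    ff = default_forcefield(
        r_short=float(ff_doc.get("r_short", 0.8)),
        r_long=float(ff_doc.get("r_long", 1.4)),
        eps_rf=float(ff_doc.get("eps_rf", 78.5)),
        cross_scale=float(ff_doc.get("cross_scale", 0.6)),
    )

    run_doc = dict(doc.get("run", {}))
    known = {f.name for f in fields(MTSConfig)}
    unknown = set(run_doc) - known
    if unknown:
        raise ValueError(f"unknown run options: {sorted(unknown)}")
    cfg = MTSConfig(**run_doc)

    equil = float(doc.get("equilibration", {}).get("time", 10.0))
    return spec, ff, cfg, equil
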