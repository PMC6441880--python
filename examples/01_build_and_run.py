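"""Build a small polar/apolar layer and run a short thermostatted MD.

Constructs a 60-water-like + 20-apolar layer, relaxes it, then runs
2 ps of single-range leap-frog dynamics with a Nose-Hoover bath per
species and prints the energy record.
"""

import mtslab as m

ff = m.default_forcefield(r_short=0.6, r_long=1.0)
spec = m.SystemSpec("layer", n_polar=60, n_apolar=20,
                    box=(2.2, 2.2, 4.4), t_init=300.0, seed=1)
state = m.build_layer(spec, ff)
print(f"built {state.topology.n_molecules} molecules "
      f"({state.topology.n_sites} sites)")

state = m.equilibrate(state, ff, t_sim=3.0, t0=300.0, seed=1)
cfg = m.MTSConfig(n_steps=1000, scheme="SR", n_m=1, n_p=5,
                  thermostat="NH", t0=300.0, seed=1)
res = m.run_simulation(state, ff, cfg)

print(res.energy[["time", "e_pot", "e_kin", "T_W", "T_C"]]
      .tail(5).to_string(index=False))
print("Columns: simulation time (ps), potential and kinetic energy "
      "(kJ/mol), and the instantaneous temperature (K) of each solvent "
      "bath; both baths should fluctuate around the 300 K target.")
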