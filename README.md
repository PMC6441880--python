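# mtslab

A self-contained molecular-dynamics laboratory for studying **numerical
artefacts of multiple-time-step (MTS) integration at liquid–liquid
interfaces** — the kind of polar/apolar boundary that biological
membranes and solvated proteins present.

In the **twin-range** (TR) scheme the nonbonded force on a site is split
by charge-group distance,

    f_i = f_i^short (r <= R_s, every step dt)
        + f_i^mid   (R_s < r <= R_l, every n_m steps),

and the mid-range part enters the leap-frog update either as a
**constant force** (CFA, the cached vector re-applied every inner step)
or as a **RESPA impulse** (n_m x the fresh force at outer steps only).
The **single-range** (SR) scheme evaluates everything within R_l every
step from a pairlist rebuilt every n_p steps.  Coupled to a global
(velocity-scaling) thermostat — weak coupling, Nosé–Hoover, or a
Nosé–Hoover chain — TR CFA integration pumps apolar density onto the
interface once the outer step n_m·dt exceeds roughly 20 fs; RESPA only
postpones the resonance to larger outer steps, while SR integration or
a stochastic-dynamics (Langevin) thermostat suppresses it.  `mtslab`
implements the full machinery — twin pairlists, LJ + reaction-field
forces, CFA/RESPA leap-frog, SHAKE, four thermostats, a Berendsen
barostat — plus a synthetic two-phase system builder and the profile
analyses needed to measure the artefact, at a desk scale that runs in
minutes.

## Worked example

`examples/` contains one short script per capability; each builds or
loads a small system, runs the method and prints what it computes.
`python examples/03_thermostats.py` compares kinetic-temperature
fluctuations of a 50-molecule Lennard-Jones bath under weak coupling
and Nosé–Hoover against the canonical law Var(T) = 2·T0²/N_f:

```
bath: 50 LJ molecules, N_f = 150, canonical Var(T) = 1200 K^2
WC: mean T =  299.8 K, Var(T) =     73 K^2, ratio to canonical = 0.06
NH: mean T =  300.0 K, Var(T) =   1055 K^2, ratio to canonical = 0.88
```

Both thermostats hold the mean at the 300 K target, but weak coupling
suppresses the fluctuations far below canonical while Nosé–Hoover
reproduces them — the distribution-width difference that separates the
two thermostat families.

`python examples/05_artefact_grid.py` runs the headline comparison in
miniature (one seed, 30 ps) on the 200+60-molecule layer and prints the
**interfacial excess** — the peak apolar density pile-up at the
interface relative to an SR reference, in units of the reference
plateau — for TR CFA Nosé–Hoover at a 20 fs outer step versus the same
mechanics under stochastic dynamics, together with the noise quantile
used for the significance call.

A thin CLI mirrors the library for shell use: `mtslab run --config
run.yaml`, `mtslab analyze density --traj traj.gro --config run.yaml`,
`mtslab grid --seeds 1 2 3`.

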