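# Methods

## Scope and model

`mtslab` is a self-contained molecular-dynamics laboratory for studying
numerical artefacts of multiple-time-step (MTS) integration at
liquid–liquid interfaces.  It integrates Newton's equations with the
leap-frog scheme,

    v(t + dt/2) = v(t - dt/2) + f(t) dt / m,
    x(t + dt)   = x(t) + v(t + dt/2) dt,

with the nonbonded force on each site split by charge-group distance
into a short-range shell (group separation r <= R_s, recomputed every
inner step dt) and a mid-range shell (R_s < r <= R_l, recomputed every
n_m steps).  The mid-range contribution enters the velocity update
either as a **constant force** (CFA — the cached vector is re-applied
unchanged at every inner step until the next refresh) or as an
**impulse** (RESPA — n_m times the fresh force at refresh steps, zero
otherwise).  The **single-range** (SR) scheme evaluates all forces
within R_l every step from one pairlist rebuilt every n_p steps; the
**twin-range** (TR) scheme uses n_m = n_p > 1.  Both degenerate setups
TR(n_m = 1) and TR(R_s = R_l) are deliberately runnable: they must
reproduce SR bit-tightly and serve as the identity checks of the MTS
machinery.

Nonbonded interactions are Lennard-Jones (C12/r^12 - C6/r^6, no
truncation smoothing) plus Coulomb with a homogeneous reaction field
representing the dielectric continuum beyond R_l:

    V(r) = f q_i q_j [ 1/r + C_rf r^2/(2 R_l^3) - (1 + C_rf/2)/R_l ],
    C_rf = 2 (eps_RF - 1) / (2 eps_RF + 1).

The constant term shifts V to zero at R_l; it affects energies, not
forces.  Cutoffs are group-based: once a molecule pair is listed, all
of its site–site terms are summed, which avoids monopole truncation
artefacts (every molecule is a neutral charge group).  There is no
long-range dispersion correction — interactions beyond R_l are simply
absent, which is part of the approximation under study.

Units are GROMOS-style (nm, ps, u, e, kJ/mol, K), with
k_B = 0.00831446 kJ mol^-1 K^-1 and the Coulomb prefactor
138.935458 kJ mol^-1 nm e^-2 fixed.

## Constraints, baths, couplers

Rigid bonds use SHAKE: mass-weighted corrections along the reference
bond vectors, Gauss–Seidel over constraints, convergence when every
constraint satisfies |d^2 - d0^2|/d0^2 <= 2*tol with tol = 1e-4
(default cap 1000 sweeps).  The implied velocity correction dx/dt is
applied to the half-step velocities.

Each solvent species is its own temperature bath; a bath's coupling
uses only its own kinetic energy and degrees of freedom.  DOF
bookkeeping: 3 per site minus the constraints inside the bath; the 3
centre-of-mass DOF (COM motion is stopped every 1 ps by default) are
charged to the all-atoms bath only.  Per-species baths therefore keep
all their 3N - K; the resulting O(1/N) temperature bias is negligible
at the sizes used.  Four couplers are implemented:

* **WC** (weak coupling): lambda = sqrt(1 + (dt/tau)(T0/T - 1)) applied
  to the updated half-step velocities, per bath (lambda floored at 0.8
  against start-up spikes).  Non-canonical kinetic-energy fluctuations
  by construction.
* **NH / NHchain** (Nose–Hoover, chain length 3 by default):
  dxi_1/dt = (2K - N_f k_B T0)/Q_1 with the standard chain coupling,
  Q_1 = N_f k_B T0 tau^2, Q_k>1 = k_B T0 tau^2; velocities are scaled
  by (1 - xi_1 dt) before the force kick (scaled leap-frog form).
* **SD** (stochastic dynamics / Langevin):
  v' = c1 v + (f/m)(1 - c1)/gamma + sigma xi with c1 = exp(-gamma dt)
  and sigma^2 = (k_B T0/m)(1 - c1^2) — the Ornstein–Uhlenbeck-exact
  discretization, chosen because it reduces to the deterministic
  leap-frog kick at gamma = 0 and has exactly the Maxwell–Boltzmann
  stationary law for free particles.
* **Berendsen semi-anisotropic barostat** (optional): mu_xy =
  [1 - kappa (dt/tau_b)(P0 - P)]^(1/2) scales the x/y box edges and
  coordinates, z fixed; P from the pair virial (including the cached
  mid-range contribution) plus a constraint-virial term from the SHAKE
  displacements.  kappa defaults to a water-like 4.5e-5 bar^-1 (the
  compressibility parameter is an assumption; it only sets the
  relaxation rate).

Default coupling parameters: tau_T = 0.1 ps, gamma = 10 ps^-1,
tau_b = 0.5 ps, inner step 2 fs, standard cutoffs 0.8/1.4 nm,
eps_RF = 78.5.

Ordering per inner step: pairlist rebuild (every n_p steps), short
forces, mid-cache refresh (every n_m steps, epochs counted from run
start), effective mid force, thermostat + kick, position update, SHAKE,
barostat, periodic COM stop.  All forces act before the constraint
projection.  Runs are bit-reproducible for a given seed.

## Synthetic systems

The generator builds desk-scale analogues of water–chloroform
layer/droplet systems from two presets: **W**, a rigid 3-site polar
solvent (SPC-like geometry: O–H 0.1 nm, H–O–H 109.47°, rigid triangle
via three distance constraints; charges -0.82/+0.41/+0.41 e; oxygen LJ
from SPC) and **C**, a single neutral LJ site (m = 119.38 u,
sigma = 0.47 nm, eps = 3.0 kJ/mol — heavy and cohesive enough to stay
liquid at 300 K).  The W–C cross interaction is the geometric mean
scaled by 0.6, which guarantees demixing; the artefact under study is a
property of the integrator, not of a specific chemistry, so any
demixing pair serves.

Molecules are placed on jittered lattices (jitter 0.02 nm per
coordinate) in disjoint regions — a polar slab below an apolar slab for
the layer geometry (stack centred in z), an apolar sphere in a polar
bath for the droplet.  All W molecules share one orientation with the
molecular plane in x-y, and the lattice spacings
(0.50, 0.50, 0.32) nm for W and 0.40 nm cubic for C are chosen so that
every intermolecular site distance is at least 0.25 nm at t = 0 for
any jitter draw; that floor caps the initial densities below the
liquid targets, so a short single-range weak-coupling run (default
10 ps) relaxes the film to liquid structure before production.
Velocities are Maxwell–Boltzmann at T_init with the total momentum
removed.

The default desk-scale layer is 200 W + 60 C in a (2.2, 2.2, 6.6) nm
box with reduced cutoffs 0.6/1.0 nm (preserving the outer-step/cutoff
regime while respecting the minimum-image bound in the small box).  At
liquid densities this filling leaves vacuum margins in z, so the
relaxed film has one polar/apolar interface in the box interior plus
two free surfaces — unlike fully periodic production systems, which
have two liquid–liquid interfaces and no free surface.  What the
generator does **not** emulate: multi-site apolar topologies,
force-field-accurate densities and surface tensions, and ns-scale
horizons; conclusions from passing tests are therefore about the
integrator's behaviour in this class of two-phase systems, not about
quantitative properties of real solvent pairs.

## Analyses

* Planar density profiles: 100 equidistant z-bins, site masses binned
  by wrapped coordinate (conserves total mass exactly per frame),
  frame-averaged; per-frame bin volumes support NPT-in-xy runs.
  Optionally the frames are recentered on a species' mass centre
  (PBC-aware) before binning; the artefact analyses recenter on the
  apolar slab, because the desk-scale film drifts inside its vacuum
  margins and uncorrected drift smears the interface over the frame
  average.
* Radial profiles: concentric shells around the droplet centre of
  mass, re-estimated per frame with circular-mean PBC unwrapping per
  axis; shell volume (4/3) pi (r_{k+1}^3 - r_k^3), so the estimator is
  noisy near the centre.
* Density differences: per-bin differences smoothed with a centred
  7-point running average (window shrinks at the edges).
* Kinetic-energy histograms: instantaneous bath temperature in 1 K
  bins, with mean and variance; the canonical reference is
  Var(T) = 2 T0^2 / N_f.
* Residence times: molecular COM z, maximal contiguous dwell runs per
  bin; a completed run of k frames dwells k * frame_period; runs
  touching the trajectory ends are discarded by default (unknown
  entry/exit) or, on request, contribute their observed span
  (k - 1) * frame_period.

## The artefact statistic and its significance

The headline comparisons are run as a grid of (scheme, application,
outer step, thermostat) cells sharing one equilibrated starting
configuration per seed.  Because the reference results are graphical
density profiles, the artefact is quantified by the **interfacial
excess**: the maximum of the 7-point-smoothed apolar density
difference (cell minus same-seed SR reference) within +-0.5 nm of the
interface, normalized by the reference apolar plateau.  The interface
is the half-plateau crossing of the smoothed apolar density on the
side facing the polar slab; the plateau is the mean over bins at
>= 80% of the apolar maximum.

A max-statistic is positively biased under sampling noise, so "excess
> 0" cannot be tested against zero directly.  Significance is instead
calibrated against an empirical null: the reference run's frames are
split into random balanced halves at 5 ps block granularity, the
statistic is computed between the half-profiles, and — since each half
carries twice the variance of a full-length profile — the
half-difference is rescaled by 1/sqrt(2) to match the noise of a
test-versus-reference comparison.  A cell's excess is significant
(one-sided, 5%) when it exceeds the 95% quantile of 200 such splits;
this is conservative in that it ignores the noise reduction from the
shared starting coordinates.  A descriptive moving-block bootstrap CI
over the test run's frames (same 5 ps blocks) is reported alongside.
Cell-level calls aggregate per-seed verdicts by majority over the
(default three) seeds.  Each thermostat family is compared against the
single-range n_p = 1 reference run with its *own* thermostat: the
stationary interface structure differs slightly between thermostats
(stochastic dynamics damps capillary modes differently from the
global-scaling couplers), and referencing across thermostats would let
that structural difference masquerade as an integration artefact.

Default production horizon is 50 ps per cell — long enough for the
resonance build-up, which sets in within a few ps at these outer
steps, while keeping the full grid a minutes-scale computation.

## Energy-conservation test design

Periodic truncated-potential liquids do not conserve an exact energy:
every charge-group pair crossing R_l jumps the bookkept potential by
the unshifted tail value, and that crossing noise is independent of the
time step.  Conservation and dt^2-scaling checks therefore use a
100-molecule LJ cluster in vacuum whose extent stays inside a far
cutoff (R_s/R_l = 1.2/4.0 nm, 9 nm box, cooled to 200 K so nothing
evaporates over the 10 ps horizon): there the measured total-energy
drift and fluctuation are purely the integrator's.  On this system the
single-range leap-frog drift is O(1e-5) of the kinetic energy over
10 ps, halving dt cuts the RMS energy fluctuation by ~4x, and the TR
CFA energy error grows strictly with n_m.  Drift is normalized by the
mean kinetic energy because the total energy of a bound cluster sits
near zero.

## Numerical choices and known limitations

* Pairlists have no Verlet skin: lists are exact at build time and
  reused unchanged for n_p steps.  This reproduces, rather than hides,
  the approximation whose consequences the package studies.
* Boundary ties: r = R_s belongs to the short shell, r = R_l to the
  mid shell (closed upper bounds).
* Group centre = centre of geometry (unweighted site mean).
* The energy series reports on-step kinetic energy from midpoint
  velocities (v(t-dt/2) + v(t+dt/2))/2, which makes the total-energy
  fluctuation of an NVE run scale as dt^2; bath temperatures for
  coupling use the half-step velocities.
* For TR runs the potential energy at off-refresh record times is
  recomputed from the current mid shell so that drift measurements use
  a consistent Hamiltonian estimate.
* The NH scaled-leap-frog form and the WC-after-kick ordering follow
  common fixed-point practice for staggered integrators; both reduce
  to plain leap-frog when on target.
* Pressure is isotropic (scalar virial); the semi-anisotropic barostat
  therefore responds to the mean pressure, which is adequate for the
  qualitative NPT checks but not for interfacial-tension work.
* Droplet-centre unwrapping assumes the droplet occupies less than
  half the box in each direction.
* Whether the reference reaction-field implementation shifts V at R_l
  is an assumption (energies only); likewise the exact residence-time
  estimator (completed-run definition above) is a documented choice.
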