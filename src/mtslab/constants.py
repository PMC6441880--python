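"""Physical constants in the internal unit system.

Internal units follow the GROMOS convention: length nm, time ps, mass u,
charge e, energy kJ/mol, temperature K.  Velocities are nm/ps and forces
kJ mol^-1 nm^-1; with these choices kinetic (1/2 m v^2) and potential
energies are directly commensurable without conversion factors.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.00831446

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
FCOUL = 138.935458

#: 1 kJ mol^-1 nm^-3 expressed in bar
PRESSURE_UNIT_BAR = 16.6054
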