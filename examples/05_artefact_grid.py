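"""The headline experiment, miniature: MTS density artefact at an interface.

Runs a single-seed, shortened version of the scheme comparison on the
desk-scale layer: a single-range reference, twin-range CFA with a
Nose-Hoover bath at a 10 fs outer step (where the resonance is
strongest at these reduced cutoffs), and the same mechanics with
stochastic dynamics.  Prints the interfacial excess statistic — the
plateau-relative apolar density pile-up at the interface relative to
the reference.  A single 30 ps run is a noisy estimate: any one value
can land below the noise quantile; the three-seed, 50 ps grid that
scripts/acceptance.py runs is what supports the aggregate conclusion
that TR CFA with a global thermostat piles density onto the interface
while SD does not.
"""

import pandas as pd

from mtslab.experiments import (ExperimentGrid, GridCell,
                                artefact_summary, desk_system, run_grid)

grid = ExperimentGrid(
    cells=[GridCell("SR", n=1, thermostat="NH"),
           GridCell("TR", "CFA", 5, "NH"),
           GridCell("SR", n=1, thermostat="SD"),
           GridCell("TR", "CFA", 5, "SD")],
    system=desk_system(),
    seeds=(1,), production=30.0, equilibration=10.0)

res = run_grid(grid, progress=lambda cell, seed:
               print(f"running {cell} (seed {seed}) ..."))
# each thermostat family against its own single-range reference, so
# thermostat-specific interface structure is not mistaken for an
# integration artefact
summary = pd.concat(
    [artefact_summary(res, ref_cell="SR_NH_np1",
                      cells=["SR_NH_np1", "TR_CFA_NH_nm5"]),
     artefact_summary(res, ref_cell="SR_SD_np1",
                      cells=["SR_SD_np1", "TR_CFA_SD_nm5"])],
    ignore_index=True)
print(summary[["cell", "n_outer_fs", "statistic", "null_q95",
               "significant"]].to_string(index=False))
print("\nstatistic: peak apolar density excess at the interface, as a "
      "fraction of the reference plateau; null_q95: the 95% noise "
      "quantile from reference-run splits. The multiple-time-step "
      "resonance artefact shows up as TR CFA NH exceeding the noise "
      "while SD stays below it (robust over seeds, not necessarily in "
      "every single short run).")
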