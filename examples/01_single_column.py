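"""Solve the canonical mid-shelf column and report preservation efficiency.

Builds the default model (7 POC pools from a gamma reactive continuum, a
4-pool DOC cascade, 2 GPS pools, lrDOC, and one mineral-phase MOC pool per
dissolved OC pool), integrates it to steady state, and prints the carbon
bookkeeping at the 1 m horizon.
"""

import numpy as np

from sedmoc import build_model, solve_steady_state
from sedmoc.diagnostics import mass_budget, preservation_efficiency

model = build_model()
state = solve_steady_state(model, n_cells=60)
print(f"converged: residual {state.residual:.2e} via {state.method}")

pe = preservation_efficiency(state)
print(f"\nPOC rain at the interface : {pe.poc_flux_surface:8.1f} umol C/cm2/yr")
print(f"POC flux at 1 m           : {pe.poc_flux_L:8.1f} umol C/cm2/yr")
print(f"net sorption over 0-1 m   : {pe.net_sorption_integral_L:8.1f} umol C/cm2/yr")
print(f"conventional PE (POC only): {pe.pe_poc:8.1f} %")
print(f"redefined PE (POC + MOC)  : {pe.pe_total:8.1f} %")
# The redefined efficiency counts carbon that left the POC pool but was
# captured on minerals as MOC before the 1 m horizon — here roughly
# doubling the apparent preservation.

budget = mass_budget(state)
print(f"\ncarbon budget sections (umol/cm2/yr): "
      f"{budget.supply:.2f} / {budget.hydrolysis_split:.2f} / {budget.fate:.2f}")
print(f"closure error: {budget.closure_error:.5f} % (acceptance bound 1 %)")

z = state.grid.z
for nm in ("O2", "DOC1", "lrDOC", "MOC_lrDOC"):
    prof = state[nm]
    print(f"{nm:10s} surface {prof[0]:10.4f}   1 m {np.interp(100, z, prof):10.4f}")
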