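"""Run the built-in validation suite.

Four independent checks: the finite-volume transport against a closed-form
advection-diffusion-decay profile; the kinetic-sorption formulation against
its equilibrium-adsorption limit (R² should round to 1.000); carbon budget
closure on the canonical column (bound 1 %); and the exact collapse of the
redefined preservation efficiency onto the conventional one when kinetic
sorption is off.
"""

from sedmoc.validation import run_validation

report = run_validation()
print("\n".join(report.lines()))
print("all checks passed" if report.passed else "FAILURE")
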