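"""Built-in validation suite: analytic transport oracle, sorption-formulation
equivalence limit, carbon mass-budget closure, and the collapse of the
redefined preservation efficiency to the conventional one when kinetic
sorption is switched off."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import SedimentConfig, SpeciesSpec, build_model
from .diagnostics import mass_budget, preservation_efficiency
from .fixtures import EQUIVALENCE_KD, fixture_config
from .solver import solve_steady_state
from .transport import assemble_operator, column_profiles, make_grid

__all__ = [
    "transport_oracle_error",
    "equivalence_r2",
    "budget_closure_error",
    "pe_collapse_gap",
    "run_validation",
    "ValidationReport",
]


def transport_oracle_error(n_cells: int = 600, D: float = 100.0,
                           v: float = 0.5, k: float = 1.0,
                           depth: float = 150.0) -> float:
    """Max relative error of the discrete steady state against the closed
    form for constant-coefficient advection–diffusion with uniform decay.

    The continuous problem D C'' − v C' − k C = 0 with C(0)=C0 on a deep
    column decays as C0·exp(r z), r = (v − sqrt(v² + 4 D k))/(2 D).  The
    column is several decay lengths deep and the comparison is restricted
    to its upper half, where the discrete bottom boundary (zero diffusive
    gradient at finite depth) does not perturb the semi-infinite solution.
    """
    sed = SedimentConfig(phi0=0.8, phi_inf=0.8, z_mix=depth,
                         alpha0=0.0, domain_depth=depth, pe_horizon=depth,
                         db0=0.0, w_inf=v)
    grid = make_grid(depth, n_cells, first_cell=depth / n_cells)
    prof = column_profiles(sed, grid)
    theta2 = 1.0 - 2.0 * np.log(0.8)
    tracer = SpeciesSpec(name="tracer", phase="dissolved", diffusible=True,
                         d_mol=D * theta2)  # apparent diffusivity exactly D
    op = assemble_operator(tracer, prof, bc_top=1.0, scheme="power")
    # steady state of accfac dC/dt = (tridiag) C + const − φ k C
    n = grid.n_cells
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, idx] = op.diag - prof.phi_c * k
    A[idx[1:], idx[1:] - 1] = op.lower[1:]
    A[idx[:-1], idx[:-1] + 1] = op.upper[:-1]
    c = np.linalg.solve(A, -op.const)
    r = (v - np.sqrt(v * v + 4.0 * D * k)) / (2.0 * D)
    exact = np.exp(r * grid.z)
    mask = grid.z <= 0.5 * depth
    return float(np.max(np.abs(c[mask] - exact[mask]) / exact[mask]))


def equivalence_r2(n_cells: int = 45, tol: float = 1e-8,
                   decimals: int | None = 3) -> float:
    """R² between the equilibrium-only and high-rate kinetic-only runs.

    Dissolved profiles are compared directly; the kinetic run's explicit
    MOC pools are compared against the equilibrium run's implicit sorbed
    load K_d·C_d.  Rounded to three decimals by default.
    """
    cfgs = fixture_config("equivalence-pair")
    st_eq = solve_steady_state(build_model(cfgs["equivalence_equilibrium"]),
                               n_cells=n_cells, tol=tol)
    st_kin = solve_steady_state(build_model(cfgs["equivalence_kinetic"]),
                                n_cells=n_cells, tol=tol)
    ref, test = [], []
    for nm in st_eq.model.dissolved_oc_names:
        ref.append(st_eq[nm])
        test.append(st_kin[nm])
        ref.append(EQUIVALENCE_KD * st_eq[nm])
        test.append(st_kin[f"MOC_{nm}"])
    a = np.concatenate(ref)
    b = np.concatenate(test)
    r2 = 1.0 - ((a - b) ** 2).sum() / ((a - a.mean()) ** 2).sum()
    return round(float(r2), decimals) if decimals is not None else float(r2)


def budget_closure_error(n_cells: int = 60, tol: float = 1e-8) -> float:
    """Carbon budget closure error (%) of the converged canonical column."""
    state = solve_steady_state(build_model(), n_cells=n_cells, tol=tol)
    return mass_budget(state).closure_error


def pe_collapse_gap(n_cells: int = 45, tol: float = 1e-8) -> float:
    """|pe_total − pe_poc| with all kinetic sorption off (exact collapse)."""
    overrides = {f"sorption.k_sorp_{cls}": 0.0 for cls in ("doc", "gps", "lrdoc")}
    state = solve_steady_state(build_model(overrides=overrides),
                               n_cells=n_cells, tol=tol)
    pe = preservation_efficiency(state)
    return abs(pe.pe_total - pe.pe_poc)


@dataclass
class ValidationReport:
    transport_error: float
    equivalence_r2: float
    budget_closure: float
    pe_collapse: float

    @property
    def passed(self) -> bool:
        return (self.transport_error < 1e-3
                and self.equivalence_r2 >= 0.9995
                and self.budget_closure <= 1.0
                and self.pe_collapse < 1e-9)

    def lines(self) -> list[str]:
        ok = lambda b: "PASS" if b else "FAIL"
        return [
            f"transport oracle   max rel error {self.transport_error:.2e} (<1e-3)  "
            f"{ok(self.transport_error < 1e-3)}",
            f"kinetic=equilibrium R^2 {self.equivalence_r2:.3f} (rounds to 1.000)  "
            f"{ok(self.equivalence_r2 >= 0.9995)}",
            f"carbon budget      closure {self.budget_closure:.4f} % (<=1 %)  "
            f"{ok(self.budget_closure <= 1.0)}",
            f"PE collapse        |pe_total-pe_poc| {self.pe_collapse:.2e} (exact)  "
            f"{ok(self.pe_collapse < 1e-9)}",
        ]


def run_validation(n_cells: int = 45) -> ValidationReport:
    return ValidationReport(
        transport_error=transport_oracle_error(),
        equivalence_r2=equivalence_r2(n_cells=n_cells),
        budget_closure=budget_closure_error(n_cells=max(n_cells, 60)),
        pe_collapse=pe_collapse_gap(n_cells=n_cells),
    )
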