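"""Monte Carlo ensemble driver: sample global parameter ranges, run the
column model per draw, and aggregate scalar outputs and depth profiles.

The default distribution table emulates a global exercise: a handful of
"gridded" inputs (sediment accumulation rate, surface porosity, SWI
concentrations of total OC, O2 and NO3) follow truncated normals or
lognormals, while kinetic and transport constants follow loguniform
distributions over literature-style ranges.  Every sampled parameter is
tagged with one of the six processes used by the importance analysis:
DOC hydrolysis, remineralization, mixing, equilibrium adsorption, kinetic
sorption and geopolymerization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .core_model import ConfigurationError, build_model
from .diagnostics import net_sorption_integral, poc_flux, preservation_efficiency
from .solver import SolverError, StateProfiles, build_system, solve_steady_state

__all__ = [
    "ParameterDistribution",
    "default_distribution_table",
    "sample_parameters",
    "EnsembleResult",
    "run_ensemble",
    "aggregate_profiles",
]

PROCESSES = [
    "DOC hydrolysis",
    "remineralization",
    "mixing",
    "equilibrium adsorption",
    "kinetic sorption",
    "geopolymerization",
]


@dataclass
class ParameterDistribution:
    """One sampled parameter: a dot-path config key, a distribution family
    with its two parameters, hard truncation bounds, the process it belongs
    to, and the transform under which the emulator should see it."""

    name: str
    family: str  # uniform | normal | lognormal | loguniform
    p1: float
    p2: float
    lo: float
    hi: float
    process: str
    transform: str = "none"  # none | log

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "normal", "lognormal", "loguniform"):
            raise ConfigurationError(f"{self.name}: unknown family {self.family!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo <= self.hi):
            raise ConfigurationError(f"{self.name}: bounds must be finite with lo ≤ hi")
        if self.process not in PROCESSES:
            raise ConfigurationError(f"{self.name}: unknown process {self.process!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample within the hard bounds (preserves the family's
        shape on the truncated support)."""
        out = np.empty(n)
        need = np.ones(n, dtype=bool)
        for _ in range(1000):
            k = int(need.sum())
            if k == 0:
                return out
            if self.family == "uniform":
                draw = rng.uniform(self.p1, self.p2, k)
            elif self.family == "normal":
                draw = rng.normal(self.p1, self.p2, k)
            elif self.family == "lognormal":
                # p1 = median, p2 = sigma of ln
                draw = np.exp(rng.normal(np.log(self.p1), self.p2, k))
            else:  # loguniform
                draw = np.exp(rng.uniform(np.log(self.p1), np.log(self.p2), k))
            ok = (draw >= self.lo) & (draw <= self.hi)
            idx = np.flatnonzero(need)[ok]
            out[idx] = draw[ok]
            need[idx] = False
        raise ConfigurationError(
            f"{self.name}: truncation to [{self.lo}, {self.hi}] leaves (almost) empty support"
        )


def default_distribution_table() -> list[ParameterDistribution]:
    """Shipped global parameter ranges (editable approximations of a global
    compilation; see the methods note for provenance of each range)."""
    P = ParameterDistribution
    log = {"transform": "log"}
    return [
        # "gridded" inputs
        P("sediment.w_inf", "lognormal", 0.03, 1.2, 0.002, 1.0, "mixing", **log),
        P("sediment.phi0", "normal", 0.85, 0.05, 0.72, 0.95, "mixing"),
        P("bc.poc_swi_wtpct", "lognormal", 1.5, 0.6, 0.2, 5.0, "DOC hydrolysis", **log),
        P("bc.o2", "lognormal", 0.15, 0.8, 0.005, 0.35, "remineralization", **log),
        P("bc.no3", "lognormal", 0.025, 0.5, 0.002, 0.06, "remineralization", **log),
        # POC hydrolysis / DOC cascade
        P("pools.a_continuum", "loguniform", 0.1, 30.0, 0.1, 30.0, "DOC hydrolysis", **log),
        P("pools.nu_continuum", "uniform", 0.10, 0.16, 0.10, 0.16, "DOC hydrolysis"),
        P("pools.lambda_doc_scale", "loguniform", 1.0, 100.0, 1.0, 100.0, "DOC hydrolysis", **log),
        P("pools.f_lrdoc_direct", "loguniform", 0.01, 0.2, 0.01, 0.2, "DOC hydrolysis", **log),
        # remineralization (reactivity classes defined by lifetimes)
        P("pools.doc_lifetime_slow", "loguniform", 0.5, 3.0, 0.5, 3.0, "remineralization", **log),
        P("pools.doc_lifetime_fast", "loguniform", 5e-4, 2e-3, 5e-4, 2e-3, "remineralization", **log),
        P("pools.gps_lifetime", "loguniform", 10.0, 40.0, 10.0, 40.0, "remineralization", **log),
        P("pools.lrdoc_lifetime", "loguniform", 8000.0, 32000.0, 8000.0, 32000.0, "remineralization", **log),
        # mixing (bioturbation, irrigation, burial)
        P("sediment.db0", "loguniform", 0.3, 50.0, 0.3, 50.0, "mixing", **log),
        P("sediment.z_mix", "uniform", 5.0, 15.0, 5.0, 15.0, "mixing"),
        P("sediment.alpha0", "loguniform", 0.3, 30.0, 0.3, 30.0, "mixing", **log),
        # equilibrium adsorption
        P("sorption.kd_eq_doc", "loguniform", 1.0, 100.0, 1.0, 100.0, "equilibrium adsorption", **log),
        P("sorption.kd_eq_gps", "loguniform", 1.0, 100.0, 1.0, 100.0, "equilibrium adsorption", **log),
        P("sorption.kd_eq_lrdoc", "loguniform", 1.0, 100.0, 1.0, 100.0, "equilibrium adsorption", **log),
        # kinetic sorption
        P("sorption.k_sorp_doc", "loguniform", 0.1, 30.0, 0.1, 30.0, "kinetic sorption", **log),
        P("sorption.k_sorp_gps", "loguniform", 0.1, 30.0, 0.1, 30.0, "kinetic sorption", **log),
        P("sorption.k_sorp_lrdoc", "loguniform", 0.1, 30.0, 0.1, 30.0, "kinetic sorption", **log),
        P("sorption.kd_sorp_doc", "loguniform", 100.0, 10000.0, 100.0, 10000.0, "kinetic sorption", **log),
        P("sorption.kd_sorp_gps", "loguniform", 100.0, 10000.0, 100.0, 10000.0, "kinetic sorption", **log),
        P("sorption.kd_sorp_lrdoc", "loguniform", 100.0, 10000.0, 100.0, 10000.0, "kinetic sorption", **log),
        # geopolymerization
        P("pools.lambda_gps_in", "loguniform", 3.0, 300.0, 3.0, 300.0, "geopolymerization", **log),
        P("pools.lambda_gps_chain", "loguniform", 0.01, 1.0, 0.01, 1.0, "geopolymerization", **log),
    ]


def distribution_table_frame(dists: list[ParameterDistribution]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in dists])


def sample_parameters(dists: list[ParameterDistribution], n: int,
                      seed: int) -> pd.DataFrame:
    """Draw ``n`` parameter vectors; reproducible under a fixed seed."""
    if n < 0:
        raise ValueError("n must be ≥0")
    rng = np.random.default_rng(seed)
    data = {d.name: d.sample(n, rng) for d in dists}
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Per-draw evaluation
# ---------------------------------------------------------------------------

SCALAR_COLUMNS = [
    "pe_poc", "pe_total", "poc_flux_surface", "poc_flux_L",
    "net_sorption_L", "moc_formation_doc", "moc_formation_gps",
    "moc_formation_lrdoc", "moc_formation_mean", "converged",
]

PROFILE_NAMES = ["pe_poc_z", "pe_total_z", "poc_flux_z", "moc_cumulative_z",
                 "sd_ratio_z", "gps_share_z"]


def evaluate_state(state: StateProfiles) -> tuple[dict, dict]:
    """Scalar outputs and depth-profile diagnostics for one converged run."""
    from .diagnostics import (lrdoc_source_attribution, moc_formation_profile,
                              sorption_desorption_ratio)

    m = state.model
    L = m.sediment.pe_horizon
    pe = preservation_efficiency(state, L)
    doc_pools = m.doc_names
    gps_pools = m.gps_names
    scalars = {
        "pe_poc": pe.pe_poc,
        "pe_total": pe.pe_total,
        "poc_flux_surface": pe.poc_flux_surface,
        "poc_flux_L": pe.poc_flux_L,
        "net_sorption_L": pe.net_sorption_integral_L,
        "moc_formation_doc": net_sorption_integral(state, L, doc_pools),
        "moc_formation_gps": net_sorption_integral(state, L, gps_pools),
        "moc_formation_lrdoc": net_sorption_integral(state, L, ["lrDOC"]),
        "converged": True,
    }
    scalars["moc_formation_mean"] = (
        scalars["moc_formation_doc"] + scalars["moc_formation_gps"]
        + scalars["moc_formation_lrdoc"]
    ) / 3.0

    z = state.grid.z
    f0 = pe.poc_flux_surface
    fz = np.array([poc_flux(state, zi) for zi in z])
    moc = moc_formation_profile(state)
    cum = moc["cumulative_integral"].to_numpy()
    profiles = {
        "pe_poc_z": 100.0 * fz / f0,
        "pe_total_z": 100.0 * (fz + cum) / f0,
        "poc_flux_z": fz,
        "moc_cumulative_z": cum,
        "sd_ratio_z": sorption_desorption_ratio(state),
        "gps_share_z": lrdoc_source_attribution(state),
    }
    return scalars, profiles


@dataclass
class EnsembleResult:
    """Per-draw parameters and outputs, plus depth-profile stacks.

    ``draws`` is the sampled parameter matrix (one row per draw), ``outputs``
    the scalar table aligned with it (NaN rows for failed draws), and
    ``profiles`` maps diagnostic names to (n_draws, n_cells) arrays.
    """

    draws: pd.DataFrame
    outputs: pd.DataFrame
    profiles: dict
    z: np.ndarray
    seed: int
    n_failed: int
    solver_options: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def converged_mask(self) -> np.ndarray:
        return self.outputs["converged"].to_numpy(dtype=bool)

    def scalar_means(self) -> pd.Series:
        ok = self.converged_mask
        return self.outputs.loc[ok].drop(columns=["converged"]).mean()

    def training_table(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(X, Y) over converged draws, for the emulator stage."""
        ok = self.converged_mask
        return self.draws.loc[ok].reset_index(drop=True), \
            self.outputs.loc[ok].drop(columns=["converged"]).reset_index(drop=True)

    def to_csv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.draws.to_csv(prefix.with_suffix(".draws.csv"), index=False)
        self.outputs.to_csv(prefix.with_suffix(".outputs.csv"), index=False)

    def to_dataset(self) -> xr.Dataset:
        ds = aggregate_profiles(self)
        ds.attrs.update(seed=self.seed, n_draws=self.n_draws, n_failed=self.n_failed)
        return ds


def run_ensemble(
    distributions: list[ParameterDistribution] | None = None,
    n: int = 150,
    seed: int = 0,
    base_overrides: dict | None = None,
    n_cells: int = 32,
    tol: float = 1e-8,
    fast: bool = True,
    draws: pd.DataFrame | None = None,
    progress: bool = False,
) -> EnsembleResult:
    """Sample parameters and solve the column model once per draw.

    Failed draws (no steady state within the fast-solver budget) are
    excluded from aggregates, counted, and never silently resampled —
    resampling would bias the parameter distribution.
    """
    if distributions is None:
        distributions = default_distribution_table()
    if draws is None:
        draws = sample_parameters(distributions, n, seed)
    if len(draws) == 0:
        raise ValueError("ensemble needs at least one draw")

    out_rows = []
    prof_stack: dict[str, list] = {nm: [] for nm in PROFILE_NAMES}
    z = None
    n_failed = 0
    iterator = draws.iterrows()
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, total=len(draws))
    for _, row in iterator:
        overrides = dict(base_overrides or {})
        overrides.update(row.to_dict())
        model = build_model(overrides=overrides, warn_unknown=False)
        try:
            state = solve_steady_state(model, n_cells=n_cells, tol=tol, fast=fast)
            scalars, profs = evaluate_state(state)
            if z is None:
                z = state.grid.z
        except (SolverError, ZeroDivisionError) as exc:
            n_failed += 1
            scalars = {k: np.nan for k in SCALAR_COLUMNS}
            scalars["converged"] = False
            profs = None
        out_rows.append(scalars)
        for nm in PROFILE_NAMES:
            prof_stack[nm].append(None if profs is None else profs[nm])

    outputs = pd.DataFrame(out_rows)[SCALAR_COLUMNS]
    if z is None:
        raise SolverError(f"all {len(draws)} ensemble draws failed")
    nz = len(z)
    profiles = {}
    for nm in PROFILE_NAMES:
        arr = np.full((len(draws), nz), np.nan)
        for i, p in enumerate(prof_stack[nm]):
            if p is not None:
                arr[i] = p
        profiles[nm] = arr
    return EnsembleResult(
        draws=draws.reset_index(drop=True), outputs=outputs, profiles=profiles,
        z=z, seed=seed, n_failed=n_failed,
        solver_options={"n_cells": n_cells, "tol": tol, "fast": fast},
    )


def aggregate_profiles(result: EnsembleResult, ci: float = 95.0) -> xr.Dataset:
    """Pointwise ensemble mean and percentile confidence band per diagnostic."""
    ok = result.converged_mask
    if ok.sum() < 2:
        raise ValueError("need at least two converged draws to aggregate")
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    data = {}
    for nm, arr in result.profiles.items():
        sel = arr[ok]
        finite = np.isfinite(sel)
        with np.errstate(invalid="ignore"):
            mean = np.where(finite.any(axis=0),
                            np.nanmean(np.where(np.isfinite(sel), sel, np.nan), axis=0),
                            np.nan)
            lo = np.nanpercentile(np.where(finite, sel, np.nan), lo_q, axis=0)
            hi = np.nanpercentile(np.where(finite, sel, np.nan), hi_q, axis=0)
        data[f"{nm}_mean"] = (("depth",), mean)
        data[f"{nm}_lo"] = (("depth",), lo)
        data[f"{nm}_hi"] = (("depth",), hi)
    return xr.Dataset(data, coords={"depth": ("depth", result.z, {"units": "cm"})})
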