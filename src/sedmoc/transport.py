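"""Sediment-column grid and conservative finite-volume transport operators.

One tridiagonal operator per species encodes, on a bulk-sediment basis,

* dissolved phase: molecular diffusion corrected for tortuosity plus
  bioturbation of the equilibrium-adsorbed fraction (mixed diffusivity
  ``φD + ρ_s ε K_d D_b``), mixed advection ``φ v_d + ρ_s ε K_d v_p``, and
  nonlocal bio-irrigation exchange ``φ α (C(0) − C(z))``;
* particulate and sorbed phases: bioturbation ``ρ_s ε D_b`` and burial
  advection ``ρ_s ε v_p``.

Face fluxes use Patankar's power-law advection–diffusion weighting by
default (pure upwind optionally), so the discrete column sum of the
operator action telescopes exactly to the net boundary flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_model import ConfigurationError, SedimentConfig, SpeciesSpec

__all__ = [
    "Grid",
    "make_grid",
    "ColumnProfiles",
    "porosity_profile",
    "burial_velocities",
    "bioturbation_profile",
    "irrigation_profile",
    "column_profiles",
    "TransportOperator",
    "assemble_operator",
]


@dataclass
class Grid:
    """Finite-volume grid: cell centers ``z`` (cm, 0 at the SWI, increasing
    downward), faces ``zf`` and widths ``dz``; geometrically refined near
    the interface where gradients are steep."""

    z: np.ndarray
    zf: np.ndarray

    def __post_init__(self) -> None:
        if self.zf[0] != 0.0 or np.any(np.diff(self.zf) <= 0):
            raise ConfigurationError("grid faces must start at 0 and strictly increase")

    @property
    def n_cells(self) -> int:
        return len(self.z)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.zf)

    @property
    def dzc(self) -> np.ndarray:
        """Center-to-center distances for interior faces (n_cells-1,)."""
        return np.diff(self.z)

    @property
    def domain_depth(self) -> float:
        return float(self.zf[-1])


def make_grid(domain_depth: float, n_cells: int = 100,
              first_cell: float = 0.1) -> Grid:
    """Geometric grid with the first cell no wider than ``first_cell`` cm."""
    if n_cells < 3:
        raise ConfigurationError("need at least 3 cells")
    dz0 = min(first_cell, domain_depth / n_cells)
    if abs(dz0 * n_cells - domain_depth) / domain_depth < 1e-12:
        zf = np.linspace(0.0, domain_depth, n_cells + 1)
    else:
        # growth ratio r: dz0 (r^n - 1)/(r - 1) = L
        def resid(r):
            return dz0 * (r ** n_cells - 1.0) / (r - 1.0) - domain_depth

        hi = 2.0
        while resid(hi) < 0:
            hi *= 2.0
        r = brentq(resid, 1.0 + 1e-12, hi)
        widths = dz0 * r ** np.arange(n_cells)
        zf = np.concatenate([[0.0], np.cumsum(widths)])
        zf[-1] = domain_depth
    z = 0.5 * (zf[:-1] + zf[1:])
    return Grid(z=z, zf=zf)


# ---------------------------------------------------------------------------
# Column property profiles
# ---------------------------------------------------------------------------

def porosity_profile(sediment: SedimentConfig, z: np.ndarray) -> np.ndarray:
    """Exponentially compacting porosity φ(z) = φ_∞ + (φ_0 − φ_∞) e^(−z/z_φ)."""
    return sediment.phi_inf + (sediment.phi0 - sediment.phi_inf) * np.exp(
        -np.asarray(z, dtype=float) / sediment.phi_atten
    )


def burial_velocities(sediment: SedimentConfig,
                      phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady-compaction burial velocities (pore water, solids), cm yr⁻¹.

    Steady compaction requires depth-invariant volumetric fluxes:
    ``φ(z) v_d(z) = φ(∞) w_inf`` and ``ε(z) v_p(z) = ε(∞) w_inf``.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1.0 - 1e-12):
        raise ConfigurationError("porosity reaches 1; burial velocity undefined")
    v_d = sediment.phi_inf * sediment.w_inf / phi
    v_p = (1.0 - sediment.phi_inf) * sediment.w_inf / (1.0 - phi)
    return v_d, v_p


def bioturbation_profile(sediment: SedimentConfig, z: np.ndarray) -> np.ndarray:
    """Constant D_b over the mixed layer, exponential decay below it."""
    z = np.asarray(z, dtype=float)
    db = np.full_like(z, sediment.db0)
    below = z > sediment.z_mix
    db[below] = sediment.db0 * np.exp(-(z[below] - sediment.z_mix) / sediment.db_atten)
    return db


def irrigation_profile(sediment: SedimentConfig, z: np.ndarray) -> np.ndarray:
    """Bio-irrigation exchange coefficient α(z) = α₀ e^(−z/z_α), yr⁻¹."""
    return sediment.alpha0 * np.exp(-np.asarray(z, dtype=float) / sediment.alpha_atten)


@dataclass
class ColumnProfiles:
    """Transport coefficient profiles evaluated at cell centers and faces."""

    grid: Grid
    sediment: SedimentConfig
    phi_c: np.ndarray
    phi_f: np.ndarray
    vd_f: np.ndarray
    vp_f: np.ndarray
    db_f: np.ndarray
    alpha_c: np.ndarray

    @property
    def eps_c(self) -> np.ndarray:
        return 1.0 - self.phi_c

    @property
    def eps_f(self) -> np.ndarray:
        return 1.0 - self.phi_f

    @property
    def tortuosity_sq_f(self) -> np.ndarray:
        """θ² = 1 − 2 ln φ (standard early-diagenesis correction)."""
        return 1.0 - 2.0 * np.log(self.phi_f)

    def apparent_diffusivity_f(self, d_mol: float) -> np.ndarray:
        return d_mol / self.tortuosity_sq_f

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy center-based export (z, phi, v_d, v_p, D_b, alpha)."""
        vd_c, vp_c = burial_velocities(self.sediment, self.phi_c)
        return pd.DataFrame({
            "z_cm": self.grid.z,
            "phi": self.phi_c,
            "v_d_cm_yr": vd_c,
            "v_p_cm_yr": vp_c,
            "D_b_cm2_yr": bioturbation_profile(self.sediment, self.grid.z),
            "alpha_yr": self.alpha_c,
        })


def column_profiles(sediment: SedimentConfig, grid: Grid) -> ColumnProfiles:
    phi_c = porosity_profile(sediment, grid.z)
    phi_f = porosity_profile(sediment, grid.zf)
    vd_f, vp_f = burial_velocities(sediment, phi_f)
    return ColumnProfiles(
        grid=grid, sediment=sediment,
        phi_c=phi_c, phi_f=phi_f, vd_f=vd_f, vp_f=vp_f,
        db_f=bioturbation_profile(sediment, grid.zf),
        alpha_c=irrigation_profile(sediment, grid.z),
    )


# ---------------------------------------------------------------------------
# Finite-volume operator
# ---------------------------------------------------------------------------

def _power_law_weight(pe: np.ndarray) -> np.ndarray:
    base = np.maximum(0.0, 1.0 - 0.1 * np.minimum(np.abs(pe), 10.0))
    return base ** 5


@dataclass
class TransportOperator:
    """Tridiagonal transport operator for a single species on a bulk basis.

    ``accfac * dC/dt = lower C_{i-1} + diag C_i + upper C_{i+1} + const``
    where ``accfac`` is the accumulation factor (``φ + ρ_s ε K_d`` for
    dissolved species, ``ρ_s ε`` for solids).  ``face_flux(C)`` returns the
    downward flux (µmol cm⁻² bulk yr⁻¹) at every cell face.
    """

    grid: Grid
    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    const: np.ndarray
    accfac: np.ndarray
    # face-flux linear form F_j = fa_j * C_{j-1} + fb_j * C_j + fc_j
    _fa: np.ndarray = field(repr=False, default=None)
    _fb: np.ndarray = field(repr=False, default=None)
    _fc: np.ndarray = field(repr=False, default=None)

    def apply(self, c: np.ndarray) -> np.ndarray:
        """Operator action (bulk volumetric rate, before dividing by accfac)."""
        out = self.diag * c + self.const
        out[1:] += self.lower[1:] * c[:-1]
        out[:-1] += self.upper[:-1] * c[1:]
        return out

    def face_flux(self, c: np.ndarray) -> np.ndarray:
        n = self.grid.n_cells
        f = self._fc.copy()
        f[1:] += self._fa[1:] * c
        f[: n] += self._fb[: n] * c
        return f


def assemble_operator(
    species: SpeciesSpec,
    profiles: ColumnProfiles,
    grid: Grid | None = None,
    *,
    bc_top: float | None = 0.0,
    bc_bottom: str = "outflow",
    scheme: str = "power",
    irrigate: bool | None = None,
) -> TransportOperator:
    """Build the finite-volume transport operator for one species.

    ``bc_top``: Dirichlet concentration at the SWI, or ``None`` for a closed
    (zero-flux) top.  ``bc_bottom``: ``"outflow"`` (zero diffusive gradient,
    advective export) or ``"closed"``.  ``scheme``: ``"power"`` (Patankar
    power-law) or ``"upwind"``.
    """
    if grid is None:
        grid = profiles.grid
    if scheme not in ("power", "upwind"):
        raise ConfigurationError(f"unknown advection scheme {scheme!r}")
    n = grid.n_cells
    rho_s = profiles.sediment.rho_s

    if species.phase == "dissolved":
        d_f = (profiles.phi_f * profiles.apparent_diffusivity_f(species.d_mol)
               + rho_s * profiles.eps_f * species.kd_eq * profiles.db_f)
        v_f = (profiles.phi_f * profiles.vd_f
               + rho_s * profiles.eps_f * species.kd_eq * profiles.vp_f)
        accfac = profiles.phi_c + rho_s * profiles.eps_c * species.kd_eq
        if irrigate is None:
            irrigate = species.diffusible
    else:
        d_f = rho_s * profiles.eps_f * profiles.db_f
        v_f = rho_s * profiles.eps_f * profiles.vp_f
        accfac = rho_s * profiles.eps_c
        irrigate = False
    if not np.all(np.isfinite(d_f)) or not np.all(np.isfinite(v_f)):
        raise ConfigurationError(f"{species.name}: non-finite transport coefficients")

    # distances from each face to the adjacent cell centers
    dist = np.empty(n + 1)
    dist[0] = grid.z[0]  # SWI to first center
    dist[1:n] = grid.dzc
    dist[n] = grid.zf[-1] - grid.z[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        dcond = np.where(d_f > 0, d_f / dist, 0.0)
        pe = np.where(d_f > 0, v_f * dist / d_f, np.inf)
    if scheme == "power":
        aw = _power_law_weight(pe)
    else:
        aw = np.zeros(n + 1)
    dterm = dcond * np.where(np.isfinite(pe), aw, 0.0)
    vplus = np.maximum(v_f, 0.0)
    vminus = np.maximum(-v_f, 0.0)

    # F_j = fa_j * C_{j-1} + fb_j * C_j + fc_j  (j = 0..n, downward positive)
    fa = dterm + vplus
    fb = -(dterm + vminus)
    fc = np.zeros(n + 1)

    if bc_top is None:
        fa[0] = fb[0] = 0.0
    else:
        fc[0] = fa[0] * float(bc_top)
        fa[0] = 0.0
    if bc_bottom == "closed":
        fa[n] = fb[n] = 0.0
    elif bc_bottom == "outflow":
        fa[n] = vplus[n]
        fb[n] = 0.0
    else:
        raise ConfigurationError(f"unknown bottom boundary {bc_bottom!r}")

    dz = grid.dz
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    const = np.zeros(n)
    lower[:] = fa[:n] / dz
    lower[0] = 0.0
    diag[:] = (fb[:n] - fa[1:]) / dz
    upper[:-1] = -fb[1:n] / dz[:-1]
    const[:] = (fc[:n] - fc[1:]) / dz

    if irrigate and profiles.sediment.alpha0 > 0:
        irr = profiles.phi_c * profiles.alpha_c
        diag -= irr
        const += irr * (float(bc_top) if bc_top is not None else 0.0)

    return TransportOperator(
        grid=grid, lower=lower, diag=diag, upper=upper, const=const,
        accfac=accfac, _fa=fa, _fb=fb, _fc=fc,
    )
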