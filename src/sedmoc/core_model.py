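"""Model definition: species registry, carbon-pool topology, parameters, boundary conditions.

The model tracks three phases in a 1-D sediment column:

* dissolved species (``µmol cm⁻³`` pore water): O2, NO3, SO4, NH4, DIC, H2S,
  CH4, Fe2, Mn2, the DOC cascade pools DOC1..DOCm, geopolymerized substances
  GPS1..GPSp and least-reactive DOC (lrDOC);
* particulate species (``µmol g⁻¹`` dry solid): iron and manganese oxide
  phases, reduced sulfur minerals and the POC reactivity pools POC1..POCn;
* sorbed species (``µmol g⁻¹`` dry solid): one mineral-phase OC (MOC) pool
  per dissolved OC pool, formed by net kinetic sorption.

Carbon moves POC→DOC1 (hydrolysis), down the DOC cascade to lower molecular
weight and higher reactivity, into GPS via geopolymerization and finally into
lrDOC, with a direct DOC1→lrDOC shortcut for freshly hydrolysed but
intrinsically undegradable material.  Every dissolved OC pool can exchange
with minerals through instantaneous equilibrium adsorption (``K_d``) and
rate-limited kinetic sorption (``k_sorp``, ``Kd_sorp``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import gammainc

__all__ = [
    "ConfigurationError",
    "DimensionError",
    "SpeciesSpec",
    "CarbonPoolConfig",
    "SedimentConfig",
    "BoundaryConditions",
    "RedoxConfig",
    "ModelDefinition",
    "build_model",
    "default_config",
    "rate_from_lifetime",
    "discretize_poc_continuum",
    "UMOL_C_PER_G_PER_WTPCT",
    "SECONDS_PER_YEAR",
]

# 1 wt% organic carbon = 0.01 g C / g solid = 1e4/12.011 µmol C / g solid
UMOL_C_PER_G_PER_WTPCT = 1.0e4 / 12.011
SECONDS_PER_YEAR = 3.15576e7
HOURS_PER_YEAR = 8766.0


class ConfigurationError(ValueError):
    """A config field is missing, out of range, or inconsistent."""


class DimensionError(ConfigurationError):
    """A rate-vector length does not match the configured pool count."""


def rate_from_lifetime(lifetime: float) -> float:
    """First-order rate constant (yr⁻¹) for a pool with the given lifetime (yr).

    Reactivity classes are specified by lifetime: (semi)labile DOC ~9 h to
    ~1.5 yr, GPS ~20 yr, lrDOC ~16,000 yr.
    """
    if not lifetime > 0:
        raise ConfigurationError(f"lifetime must be positive, got {lifetime}")
    return 1.0 / lifetime


# ---------------------------------------------------------------------------
# Reactive-continuum discretization of POC
# ---------------------------------------------------------------------------

# Dimensionless support u = a*k over which the gamma continuum is binned.
# Mass outside [U_MIN, U_MAX] is folded into the extreme pools.
_U_MIN = 1.0e-7
_U_MAX = 10.0


def discretize_poc_continuum(
    a: float, nu: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a gamma reactive continuum into ``n`` first-order POC pools.

    The continuum assigns initial mass density ``f(k) ∝ k^(nu-1) exp(-a k)``
    to hydrolysis rate constants ``k`` (a gamma distribution with shape
    ``nu`` and scale ``1/a``), so that total mass decays as
    ``G(t) = (a/(a+t))^nu``.  Pools are formed by log-spaced bins in the
    dimensionless variable ``u = a k``; each pool carries the bin's gamma
    mass at the bin's geometric-midpoint rate constant.  Because the bins
    are defined in ``u``, doubling ``a`` exactly halves every rate constant
    and leaves the fractions unchanged.

    Parameters
    ----------
    a : float
        Age parameter of the continuum (yr); larger ``a`` means less
        reactive material overall.
    nu : float
        Shape parameter (0 < nu < 1); small values spread reactivity over
        many orders of magnitude.
    n : int
        Number of discrete pools (≥1), ordered from most to least reactive.

    Returns
    -------
    k_hyd : ndarray, shape (n,)
        Hydrolysis rate constants (yr⁻¹), strictly decreasing.
    fractions : ndarray, shape (n,)
        Initial mass fractions, summing to 1.
    """
    if not a > 0:
        raise ConfigurationError(f"continuum age parameter a must be >0, got {a}")
    if not 0 < nu < 1:
        raise ConfigurationError(f"continuum shape nu must be in (0,1), got {nu}")
    if n < 1:
        raise ConfigurationError(f"pool count must be ≥1, got {n}")
    if n == 1:
        # single pool: mean rate of the continuum, nu/a
        return np.array([nu / a]), np.array([1.0])

    edges = np.logspace(math.log10(_U_MIN), math.log10(_U_MAX), n + 1)
    cdf = gammainc(nu, edges)  # regularized lower incomplete gamma
    frac = np.diff(cdf)
    # fold tail mass into the extreme bins
    frac[0] += cdf[0]
    frac[-1] += 1.0 - cdf[-1]
    frac /= frac.sum()

    k = np.sqrt(edges[:-1] * edges[1:]) / a
    # order from most to least reactive (POC1 most labile)
    order = np.argsort(k)[::-1]
    return k[order], frac[order]


def continuum_survival(a: float, nu: float, t: float) -> float:
    """Closed-form surviving mass fraction of the gamma continuum at time t."""
    return (a / (a + t)) ** nu


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One model species.

    Units are per phase: dissolved µmol cm⁻³ pore water, particulate and
    sorbed µmol g⁻¹ dry solid.  ``kd_eq`` is the linear equilibrium
    partition coefficient K_d (cm³ g⁻¹); ``k_sorp`` (yr⁻¹) and ``kd_sorp``
    (cm³ g⁻¹) parameterize kinetic exchange with the ``sorbed_partner``
    MOC pool.
    """

    name: str
    phase: str  # dissolved | particulate | sorbed
    unit: str = ""
    diffusible: bool = False
    d_mol: float = 0.0  # molecular diffusivity, cm² yr⁻¹ (dissolved only)
    kd_eq: float = 0.0
    k_sorp: float = 0.0
    kd_sorp: float = 1.0
    sorbed_partner: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("dissolved", "particulate", "sorbed"):
            raise ConfigurationError(f"{self.name}: unknown phase {self.phase!r}")
        if not self.unit:
            self.unit = (
                "umol cm-3 pore water" if self.phase == "dissolved" else "umol g-1 dry solid"
            )
        if self.kd_eq < 0:
            raise ConfigurationError(f"{self.name}: kd_eq must be ≥0")
        if self.k_sorp < 0:
            raise ConfigurationError(f"{self.name}: k_sorp must be ≥0")
        if self.k_sorp > 0 and not self.kd_sorp > 0:
            raise ConfigurationError(f"{self.name}: kd_sorp must be >0 when k_sorp>0")
        if self.k_sorp > 0 and self.sorbed_partner is None:
            raise ConfigurationError(f"{self.name}: k_sorp>0 requires a sorbed_partner")


@dataclass
class CarbonPoolConfig:
    """Topology and rate constants of the organic-carbon pool network."""

    n_poc: int = 7
    m_doc: int = 4
    p_gps: int = 2
    k_hyd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    poc_fractions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lambda_doc: np.ndarray = field(default_factory=lambda: np.zeros(0))  # DOC_i -> DOC_{i+1}
    f_lrdoc_direct: float = 0.05
    lambda_gps: np.ndarray = field(default_factory=lambda: np.zeros(0))  # DOC_m->GPS1->..->lrDOC
    k_remin_doc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    k_remin_gps: float = rate_from_lifetime(20.0)
    k_remin_lrdoc: float = rate_from_lifetime(16000.0)

    def validate(self) -> None:
        if min(self.n_poc, self.m_doc, self.p_gps) < 1:
            raise ConfigurationError("pool counts n_poc, m_doc, p_gps must all be ≥1")
        if len(self.k_hyd) != self.n_poc or len(self.poc_fractions) != self.n_poc:
            raise DimensionError(
                f"k_hyd/poc_fractions length {len(self.k_hyd)}/{len(self.poc_fractions)} "
                f"vs n_poc={self.n_poc}"
            )
        if len(self.lambda_doc) != self.m_doc - 1:
            raise DimensionError(
                f"lambda_doc needs m_doc-1={self.m_doc - 1} entries, got {len(self.lambda_doc)}"
            )
        if len(self.lambda_gps) != self.p_gps + 1:
            raise DimensionError(
                f"lambda_gps needs p_gps+1={self.p_gps + 1} entries "
                f"(DOC_m→GPS1, chain, GPS_p→lrDOC), got {len(self.lambda_gps)}"
            )
        if len(self.k_remin_doc) != self.m_doc:
            raise DimensionError(
                f"k_remin_doc needs m_doc={self.m_doc} entries, got {len(self.k_remin_doc)}"
            )
        for nm, arr in (
            ("k_hyd", self.k_hyd),
            ("poc_fractions", self.poc_fractions),
            ("lambda_doc", self.lambda_doc),
            ("lambda_gps", self.lambda_gps),
            ("k_remin_doc", self.k_remin_doc),
        ):
            if np.any(np.asarray(arr) < 0):
                raise ConfigurationError(f"{nm} must be non-negative")
        if not 0 <= self.f_lrdoc_direct <= 1:
            raise ConfigurationError(
                f"f_lrdoc_direct must be in [0,1], got {self.f_lrdoc_direct}"
            )
        if abs(self.poc_fractions.sum() - 1.0) > 1e-9:
            raise ConfigurationError("poc_fractions must sum to 1")
        # reactivity ordering across the three classes
        if not (min(self.k_remin_doc) > self.k_remin_gps > self.k_remin_lrdoc):
            raise ConfigurationError(
                "reactivity classes must be strictly ordered: "
                "min (semi)labile remineralization > GPS > lrDOC"
            )


@dataclass
class SedimentConfig:
    """Column geometry, compaction, mixing and burial parameters."""

    water_depth: float = 150.0  # m (contextual; not used dynamically)
    temperature: float = 8.0  # °C
    salinity: float = 35.0  # PSU
    phi0: float = 0.85  # surface porosity
    phi_inf: float = 0.70  # compacted porosity
    phi_atten: float = 30.0  # porosity e-folding depth, cm
    rho_s: float = 2.5  # dry solid density, g cm⁻³
    w_inf: float = 0.1  # burial velocity at compacted depth, cm yr⁻¹
    db0: float = 10.0  # surface bioturbation coefficient, cm² yr⁻¹
    z_mix: float = 10.0  # mixed-layer depth, cm
    db_atten: float = 3.0  # bioturbation decay scale below z_mix, cm
    alpha0: float = 5.0  # bio-irrigation exchange coefficient at surface, yr⁻¹
    alpha_atten: float = 5.0  # irrigation decay scale, cm
    domain_depth: float = 500.0  # cm
    pe_horizon: float = 100.0  # L in the preservation-efficiency integrals, cm

    def validate(self) -> None:
        if not (0 < self.phi_inf <= self.phi0 < 1):
            raise ConfigurationError(
                f"need 0 < phi_inf ≤ phi0 < 1; got phi0={self.phi0}, phi_inf={self.phi_inf}"
            )
        for nm in ("phi_atten", "rho_s", "w_inf", "z_mix", "db_atten",
                   "alpha_atten", "domain_depth", "pe_horizon"):
            if not getattr(self, nm) > 0:
                raise ConfigurationError(f"{nm} must be >0, got {getattr(self, nm)}")
        for nm in ("db0", "alpha0"):
            if getattr(self, nm) < 0:
                raise ConfigurationError(f"{nm} must be ≥0, got {getattr(self, nm)}")
        if self.pe_horizon > self.domain_depth:
            raise ConfigurationError(
                f"pe_horizon={self.pe_horizon} exceeds domain_depth={self.domain_depth}"
            )


@dataclass
class BoundaryConditions:
    """Concentrations at the sediment–water interface (z = 0).

    Dissolved entries are µmol cm⁻³; particulate and sorbed entries are
    µmol g⁻¹ dry solid.  The bottom boundary is zero-gradient for all
    species.  MOC pools default to zero at the interface: mineral-phase OC
    is formed within the sediment, not delivered from the water column.
    """

    swi_dissolved: dict[str, float] = field(default_factory=dict)
    swi_particulate: dict[str, float] = field(default_factory=dict)
    swi_sorbed: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for group in (self.swi_dissolved, self.swi_particulate, self.swi_sorbed):
            for name, val in group.items():
                if val < 0:
                    raise ConfigurationError(f"SWI concentration of {name} is negative: {val}")

    def value(self, name: str) -> float:
        for group in (self.swi_dissolved, self.swi_particulate, self.swi_sorbed):
            if name in group:
                return group[name]
        return 0.0


@dataclass
class RedoxConfig:
    """Kinetic constants of the remineralization ladder and secondary redox network.

    Half-saturation / inhibition constants are µmol cm⁻³ for dissolved
    acceptors and µmol g⁻¹ for mineral oxides.  Bimolecular constants are
    cm³ µmol⁻¹ yr⁻¹ (dissolved–dissolved) or g µmol⁻¹ yr⁻¹ where one
    reactant is a solid.  ``cn_ratio`` is the molar C:N of hydrolysable
    organic matter (Redfield by default).
    """

    km_o2: float = 0.008
    km_no3: float = 0.004
    km_mno2: float = 4.0
    km_feoh3: float = 65.0
    km_so4: float = 1.6
    kin_o2: float = 0.008
    kin_no3: float = 0.004
    kin_mno2: float = 4.0
    kin_feoh3: float = 65.0
    kin_so4: float = 1.6
    k_fe_ox: float = 1.0e4     # Fe2 + O2 -> FeOH3_HR
    k_mn_ox: float = 1.0e3     # Mn2 + O2 -> MnO2
    k_h2s_ox: float = 1.6e2    # H2S + O2 -> SO4
    k_ch4_ox: float = 1.0e4    # CH4 + O2 -> DIC
    k_aom: float = 10.0        # CH4 + SO4 -> DIC + H2S
    k_fes_ppt: float = 1.0     # Fe2 + H2S -> FeS
    k_fes_diss: float = 1.0e-3 # FeS -> Fe2 + H2S (first order, yr⁻¹)
    k_fes2: float = 1.0e-1     # FeS + S0 -> FeS2
    k_s0_disp: float = 3.0     # 4 S0 -> 3 H2S + SO4 (first order, yr⁻¹)
    k_h2s_feoh3: float = 1.0e-2  # H2S + 2 FeOH3 -> S0 + 2 Fe2
    k_h2s_mno2: float = 1.0e-2   # H2S + MnO2 -> S0 + Mn2
    cn_ratio: float = 106.0 / 16.0

    def validate(self) -> None:
        for nm, val in asdict(self).items():
            if val < 0:
                raise ConfigurationError(f"redox constant {nm} must be ≥0, got {val}")


# dissolved inventory (non-OC), with Boudreau-style linear fits for molecular
# diffusivity D0 = (m0 + m1*T) in 1e-6 cm² s⁻¹
_DIFFUSIVITY_FITS = {
    "O2": (11.70, 0.344),
    "NO3": (9.72, 0.365),
    "SO4": (4.96, 0.226),
    "NH4": (9.76, 0.398),
    "DIC": (5.06, 0.275),   # as HCO3-
    "H2S": (10.40, 0.273),  # as HS-
    "CH4": (9.80, 0.300),
    "Fe2": (3.31, 0.150),
    "Mn2": (3.04, 0.153),
}
# large organic molecules: MW-dependent, far slower than small ions
_DOC_DIFFUSIVITY_RANGE = (0.5, 1.5)  # 1e-6 cm² s⁻¹ across DOC1 (high MW) .. DOCm (low MW)
_GPS_DIFFUSIVITY = 0.3
_LRDOC_DIFFUSIVITY = 0.3

_CM2_PER_YR = SECONDS_PER_YEAR * 1.0e-6  # (1e-6 cm² s⁻¹) -> cm² yr⁻¹

_PARTICULATE_INORGANIC = ["FeOH3_HR", "FeOH3_MR", "FeOH3_UR", "MnO2", "FeS", "FeS2", "S0"]


@dataclass
class ModelDefinition:
    """A fully parameterized sediment-column model."""

    species: list[SpeciesSpec]
    pools: CarbonPoolConfig
    sediment: SedimentConfig
    bcs: BoundaryConditions
    redox: RedoxConfig
    config: dict = field(default_factory=dict)  # resolved flat config

    # ---- derived registries -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def by_phase(self, phase: str) -> list[SpeciesSpec]:
        return [s for s in self.species if s.phase == phase]

    @property
    def doc_names(self) -> list[str]:
        return [f"DOC{i + 1}" for i in range(self.pools.m_doc)]

    @property
    def gps_names(self) -> list[str]:
        return [f"GPS{i + 1}" for i in range(self.pools.p_gps)]

    @property
    def poc_names(self) -> list[str]:
        return [f"POC{i + 1}" for i in range(self.pools.n_poc)]

    @property
    def dissolved_oc_names(self) -> list[str]:
        return self.doc_names + self.gps_names + ["lrDOC"]

    @property
    def moc_names(self) -> list[str]:
        return [f"MOC_{n}" for n in self.dissolved_oc_names]

    def spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self) -> None:
        self.pools.validate()
        self.sediment.validate()
        self.bcs.validate()
        self.redox.validate()
        names = self.species_names
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")
        expected_dissolved = (
            ["O2", "SO4", "NH4", "NO3", "DIC", "H2S", "CH4", "Fe2", "Mn2"]
            + self.dissolved_oc_names
        )
        have_dissolved = [s.name for s in self.by_phase("dissolved")]
        if set(have_dissolved) != set(expected_dissolved):
            raise ConfigurationError(
                f"dissolved inventory mismatch: {sorted(set(expected_dissolved) ^ set(have_dissolved))}"
            )
        expected_part = _PARTICULATE_INORGANIC + self.poc_names
        have_part = [s.name for s in self.by_phase("particulate")]
        if set(have_part) != set(expected_part):
            raise ConfigurationError("particulate inventory mismatch")
        if set(s.name for s in self.by_phase("sorbed")) != set(self.moc_names):
            raise ConfigurationError("sorbed inventory must be one MOC pool per dissolved OC pool")
        for nm in self.dissolved_oc_names:
            sp = self.spec(nm)
            if sp.k_sorp > 0 and sp.sorbed_partner != f"MOC_{nm}":
                raise ConfigurationError(f"{nm}: sorbed_partner must be MOC_{nm}")

    # ---- serialization ------------------------------------------------------
    def summary(self) -> dict:
        """JSON-ready structured summary of the model."""
        return {
            "n_species": len(self.species),
            "pools": {
                "n_poc": self.pools.n_poc,
                "m_doc": self.pools.m_doc,
                "p_gps": self.pools.p_gps,
                "k_hyd": list(map(float, self.pools.k_hyd)),
                "poc_fractions": list(map(float, self.pools.poc_fractions)),
                "k_remin_doc": list(map(float, self.pools.k_remin_doc)),
                "k_remin_gps": self.pools.k_remin_gps,
                "k_remin_lrdoc": self.pools.k_remin_lrdoc,
                "lambda_doc": list(map(float, self.pools.lambda_doc)),
                "lambda_gps": list(map(float, self.pools.lambda_gps)),
                "f_lrdoc_direct": self.pools.f_lrdoc_direct,
            },
            "sediment": asdict(self.sediment),
            "species": [
                {k: v for k, v in asdict(s).items()} for s in self.species
            ],
            "config": _jsonable(self.config),
        }

    def dump_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Default configuration (the canonical mid-shelf column)
# ---------------------------------------------------------------------------

def default_config() -> dict[str, float]:
    """Canonical single-site configuration: a mid-shelf muddy sediment column.

    Flat dictionary with namespaced keys; any key can be overridden when
    building a model.  Units follow the type docstrings.
    """
    cfg: dict[str, float] = {
        # sediment column
        "sediment.water_depth": 150.0,
        "sediment.temperature": 8.0,
        "sediment.salinity": 35.0,
        "sediment.phi0": 0.85,
        "sediment.phi_inf": 0.70,
        "sediment.phi_atten": 30.0,
        "sediment.rho_s": 2.5,
        "sediment.w_inf": 0.1,
        "sediment.db0": 10.0,
        "sediment.z_mix": 10.0,
        "sediment.db_atten": 3.0,
        "sediment.alpha0": 5.0,
        "sediment.alpha_atten": 5.0,
        "sediment.domain_depth": 500.0,
        "sediment.pe_horizon": 100.0,
        # carbon pools
        "pools.n_poc": 7,
        "pools.m_doc": 4,
        "pools.p_gps": 2,
        "pools.a_continuum": 2.0,  # yr; mixed fresh/aged material at a shelf SWI
        "pools.nu_continuum": 0.125,
        "pools.doc_lifetime_slow": 1.5,  # yr, DOC1 (high MW)
        "pools.doc_lifetime_fast": 9.0 / HOURS_PER_YEAR,  # 9 h, DOCm (low MW)
        "pools.gps_lifetime": 20.0,  # yr
        "pools.lrdoc_lifetime": 16000.0,  # yr
        "pools.lambda_doc_scale": 10.0,  # yr⁻¹, DOC_i -> DOC_{i+1}
        "pools.lambda_gps_in": 30.0,  # yr⁻¹, DOC_m -> GPS1
        "pools.lambda_gps_chain": 0.1,  # yr⁻¹, GPS1 -> GPS2 -> lrDOC
        "pools.f_lrdoc_direct": 0.05,
        # sorption, per reactivity class
        "sorption.kd_eq_doc": 10.0,
        "sorption.kd_eq_gps": 10.0,
        "sorption.kd_eq_lrdoc": 10.0,
        "sorption.k_sorp_doc": 3.0,
        "sorption.k_sorp_gps": 3.0,
        "sorption.k_sorp_lrdoc": 3.0,
        "sorption.kd_sorp_doc": 1000.0,
        "sorption.kd_sorp_gps": 1000.0,
        "sorption.kd_sorp_lrdoc": 1000.0,
        # SWI boundary concentrations, dissolved (µmol cm⁻³)
        "bc.o2": 0.20,
        "bc.no3": 0.030,
        "bc.so4": 28.0,
        "bc.nh4": 0.001,
        "bc.dic": 2.2,
        "bc.h2s": 0.0,
        "bc.ch4": 0.0,
        "bc.fe2": 0.0,
        "bc.mn2": 0.0,
        "bc.doc1": 0.010,
        "bc.lrdoc": 0.030,
        # SWI boundary, particulate
        "bc.poc_swi_wtpct": 1.5,  # total OC at SWI, weight %
        "bc.feoh3_hr": 30.0,
        "bc.feoh3_mr": 30.0,
        "bc.feoh3_ur": 50.0,
        "bc.mno2": 5.0,
        "bc.fes": 0.0,
        "bc.fes2": 0.0,
        "bc.s0": 0.0,
    }
    for nm, val in asdict(RedoxConfig()).items():
        cfg[f"redox.{nm}"] = val
    return cfg


def _load_config_document(source) -> dict:
    """Accept a dict, a YAML/JSON path, or YAML text."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    p = Path(source)
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping of namespaced keys")
    # allow nested documents: flatten to dotted keys
    flat: dict = {}

    def _flatten(prefix, obj):
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                _flatten(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            flat[prefix] = obj

    _flatten("", doc)
    return flat


def build_model(config=None, overrides: Mapping | None = None,
                warn_unknown: bool = True) -> ModelDefinition:
    """Build a validated :class:`ModelDefinition` from a configuration.

    ``config`` may be ``None`` (all defaults), a flat/nested mapping, or a
    path to a YAML/JSON document.  ``overrides`` is applied on top.  Unknown
    keys produce a warning, not an error.
    """
    import warnings

    cfg = default_config()
    user = _load_config_document(config)
    if overrides:
        user.update(overrides)
    optional_keys = {"pools.k_hyd", "pools.poc_fractions"}
    for key, val in user.items():
        if key in optional_keys:
            continue  # consumed directly below
        if warn_unknown and key not in cfg:
            warnings.warn(f"unknown config key {key!r} (ignored)", stacklevel=2)
            continue
        cfg[key] = val

    def g(key):
        return cfg[key]

    sediment = SedimentConfig(
        water_depth=g("sediment.water_depth"), temperature=g("sediment.temperature"),
        salinity=g("sediment.salinity"), phi0=g("sediment.phi0"),
        phi_inf=g("sediment.phi_inf"), phi_atten=g("sediment.phi_atten"),
        rho_s=g("sediment.rho_s"), w_inf=g("sediment.w_inf"), db0=g("sediment.db0"),
        z_mix=g("sediment.z_mix"), db_atten=g("sediment.db_atten"),
        alpha0=g("sediment.alpha0"), alpha_atten=g("sediment.alpha_atten"),
        domain_depth=g("sediment.domain_depth"), pe_horizon=g("sediment.pe_horizon"),
    )
    sediment.validate()

    n_poc = int(g("pools.n_poc"))
    m_doc = int(g("pools.m_doc"))
    p_gps = int(g("pools.p_gps"))
    if min(n_poc, m_doc, p_gps) < 1:
        raise ConfigurationError("pool counts pools.n_poc/m_doc/p_gps must be ≥1")

    if "pools.k_hyd" in user:
        k_hyd = np.asarray(user["pools.k_hyd"], dtype=float)
        fracs = np.asarray(user.get("pools.poc_fractions",
                                    np.full(n_poc, 1.0 / n_poc)), dtype=float)
    else:
        k_hyd, fracs = discretize_poc_continuum(
            g("pools.a_continuum"), g("pools.nu_continuum"), n_poc
        )

    # remineralization of the (semi)labile cascade: lifetimes log-spaced from
    # slow (DOC1, high MW) to fast (DOCm, low MW)
    life_slow = g("pools.doc_lifetime_slow")
    life_fast = g("pools.doc_lifetime_fast")
    if m_doc == 1:
        k_remin_doc = np.array([rate_from_lifetime(life_slow)])
    else:
        lives = np.logspace(math.log10(life_slow), math.log10(life_fast), m_doc)
        k_remin_doc = 1.0 / lives

    lam_scale = float(g("pools.lambda_doc_scale"))
    lambda_doc = np.full(max(m_doc - 1, 0), lam_scale)
    lambda_gps = np.concatenate([
        [float(g("pools.lambda_gps_in"))],
        np.full(p_gps, float(g("pools.lambda_gps_chain"))),
    ])
    pools = CarbonPoolConfig(
        n_poc=n_poc, m_doc=m_doc, p_gps=p_gps,
        k_hyd=k_hyd, poc_fractions=fracs,
        lambda_doc=lambda_doc, f_lrdoc_direct=float(g("pools.f_lrdoc_direct")),
        lambda_gps=lambda_gps, k_remin_doc=k_remin_doc,
        k_remin_gps=rate_from_lifetime(g("pools.gps_lifetime")),
        k_remin_lrdoc=rate_from_lifetime(g("pools.lrdoc_lifetime")),
    )
    pools.validate()

    redox_kwargs = {nm: cfg[f"redox.{nm}"] for nm in asdict(RedoxConfig())}
    redox = RedoxConfig(**redox_kwargs)
    redox.validate()

    T = sediment.temperature
    species: list[SpeciesSpec] = []
    for nm, (m0, m1) in _DIFFUSIVITY_FITS.items():
        species.append(SpeciesSpec(
            name=nm, phase="dissolved", diffusible=True,
            d_mol=(m0 + m1 * T) * _CM2_PER_YR,
        ))

    def _oc_species(name: str, klass: str, d_mol_1e6: float) -> SpeciesSpec:
        return SpeciesSpec(
            name=name, phase="dissolved", diffusible=True,
            d_mol=d_mol_1e6 * _CM2_PER_YR,
            kd_eq=float(g(f"sorption.kd_eq_{klass}")),
            k_sorp=float(g(f"sorption.k_sorp_{klass}")),
            kd_sorp=float(g(f"sorption.kd_sorp_{klass}")),
            sorbed_partner=f"MOC_{name}",
        )

    d_doc = np.linspace(*_DOC_DIFFUSIVITY_RANGE, m_doc)
    for i in range(m_doc):
        species.append(_oc_species(f"DOC{i + 1}", "doc", d_doc[i]))
    for j in range(p_gps):
        species.append(_oc_species(f"GPS{j + 1}", "gps", _GPS_DIFFUSIVITY))
    species.append(_oc_species("lrDOC", "lrdoc", _LRDOC_DIFFUSIVITY))

    for nm in _PARTICULATE_INORGANIC:
        species.append(SpeciesSpec(name=nm, phase="particulate"))
    for i in range(n_poc):
        species.append(SpeciesSpec(name=f"POC{i + 1}", phase="particulate"))
    for nm in [f"DOC{i + 1}" for i in range(m_doc)] + [f"GPS{j + 1}" for j in range(p_gps)] + ["lrDOC"]:
        species.append(SpeciesSpec(name=f"MOC_{nm}", phase="sorbed"))

    # boundary conditions
    poc_total = float(g("bc.poc_swi_wtpct")) * UMOL_C_PER_G_PER_WTPCT  # µmol C g⁻¹
    swi_particulate = {
        "FeOH3_HR": float(g("bc.feoh3_hr")), "FeOH3_MR": float(g("bc.feoh3_mr")),
        "FeOH3_UR": float(g("bc.feoh3_ur")), "MnO2": float(g("bc.mno2")),
        "FeS": float(g("bc.fes")), "FeS2": float(g("bc.fes2")), "S0": float(g("bc.s0")),
    }
    for i in range(n_poc):
        swi_particulate[f"POC{i + 1}"] = poc_total * float(fracs[i])
    swi_dissolved = {
        "O2": float(g("bc.o2")), "NO3": float(g("bc.no3")), "SO4": float(g("bc.so4")),
        "NH4": float(g("bc.nh4")), "DIC": float(g("bc.dic")), "H2S": float(g("bc.h2s")),
        "CH4": float(g("bc.ch4")), "Fe2": float(g("bc.fe2")), "Mn2": float(g("bc.mn2")),
        "DOC1": float(g("bc.doc1")), "lrDOC": float(g("bc.lrdoc")),
    }
    for i in range(1, m_doc):
        swi_dissolved[f"DOC{i + 1}"] = 0.0
    for j in range(p_gps):
        swi_dissolved[f"GPS{j + 1}"] = 0.0
    swi_sorbed = {f"MOC_{nm}": 0.0
                  for nm in [f"DOC{i + 1}" for i in range(m_doc)]
                  + [f"GPS{j + 1}" for j in range(p_gps)] + ["lrDOC"]}
    bcs = BoundaryConditions(swi_dissolved, swi_particulate, swi_sorbed)
    bcs.validate()

    model = ModelDefinition(species=species, pools=pools, sediment=sediment,
                            bcs=bcs, redox=redox, config=cfg)
    model.validate()
    return model
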