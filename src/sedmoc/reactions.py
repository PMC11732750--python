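"""Reaction-rate terms: hydrolysis, DOC cascade, geopolymerization,
remineralization redox ladder, secondary redox network and kinetic sorption.

All rates returned by :class:`ReactionNetwork.rates` are on a bulk-sediment
volumetric basis (µmol cm⁻³ bulk yr⁻¹): dissolved-phase first-order
remineralization enters as ``φ k C_d``, solid-phase terms as
``ρ_s ε R_p``, and the kinetic sorption exchange and cascade transfer terms
as written in the governing equations (no porosity prefactor), which keeps
the dissolved and sorbed equations mutually conservative.

Carbon bookkeeping is closed by construction: every transformation moves
carbon 1:1 between pools, and remineralization moves it 1:1 into DIC (half
into CH4 for methanogenesis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ConfigurationError, ModelDefinition, RedoxConfig
from .transport import ColumnProfiles

__all__ = [
    "hydrolysis_rates",
    "cascade_rates",
    "chain_rates",
    "geopolymerization_rates",
    "sorption_exchange",
    "redox_partition",
    "ReactionNetwork",
]

PATHWAYS = ["O2", "NO3", "MnO2", "FeOH3", "SO4", "CH4"]


def _softpos(c, delta):
    """Smooth positive part, ``0.5 (c + sqrt(c² + δ²))``.

    C¹ replacement for ``max(c, 0)`` so that Newton-type steady-state
    iterations see a differentiable rate law; δ is far below any
    concentration of interest.
    """
    c = np.asarray(c, dtype=float)
    return 0.5 * (c + np.sqrt(c * c + delta * delta))


def _gated_product(a, b, delta_a, delta_b):
    """Bimolecular product ``a·b`` gated off in the double-negative quadrant.

    Exact mass action wherever either concentration is positive (so a
    transiently negative reactant sees a linear restoring term), smoothly
    suppressed when both are negative — the configuration in which a raw
    product would self-amplify.  C¹ everywhere; the δ's only set the gate
    steepness, not the rates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    neg_a = 0.5 * (1.0 - a / (np.abs(a) + delta_a))
    neg_b = 0.5 * (1.0 - b / (np.abs(b) + delta_b))
    return a * b * (1.0 - neg_a * neg_b)


# ---------------------------------------------------------------------------
# Elementary rate expressions (pure algebra, unit-agnostic)
# ---------------------------------------------------------------------------

def hydrolysis_rates(poc: np.ndarray, k_hyd: np.ndarray) -> np.ndarray:
    """First-order multi-G hydrolysis sinks, k_i * C_p,i (same units as C/yr)."""
    poc = np.asarray(poc, dtype=float)
    k = np.asarray(k_hyd, dtype=float)
    if poc.shape[-1] != k.shape[0]:
        raise ConfigurationError("k_hyd length does not match POC pool count")
    return k * poc


def chain_rates(pools: np.ndarray, lam_out: np.ndarray) -> np.ndarray:
    """Net rates of a linear first-order chain.

    ``pools[..., i]`` feeds ``pools[..., i+1]`` at rate ``lam_out[i]``; the
    last ``lam_out`` entry exports from the final pool.  Returns net rates
    per pool plus the exported flux as the final column; columns sum to zero
    (total mass in chain + export conserved).
    """
    pools = np.asarray(pools, dtype=float)
    lam = np.asarray(lam_out, dtype=float)
    if pools.shape[-1] != lam.shape[0]:
        raise ConfigurationError("chain rate-vector length mismatch")
    out = lam * pools
    net = np.empty(pools.shape[:-1] + (pools.shape[-1] + 1,))
    net[..., 0] = -out[..., 0]
    net[..., 1:-1] = out[..., :-1] - out[..., 1:]
    net[..., -1] = out[..., -1]
    return net


def cascade_rates(doc: np.ndarray, lambda_doc: np.ndarray) -> np.ndarray:
    """Sequential-hydrolysis net rates for the DOC cascade.

    ``lambda_doc[i]`` converts DOC_{i+1} into DOC_{i+2} (m-1 entries for m
    pools); the cascade itself conserves carbon, so the net rates sum to 0.
    """
    doc = np.asarray(doc, dtype=float)
    lam = np.asarray(lambda_doc, dtype=float)
    m = doc.shape[-1]
    if lam.shape[0] != m - 1:
        raise ConfigurationError(f"lambda_doc needs {m - 1} entries, got {lam.shape[0]}")
    net = np.zeros_like(doc)
    if m == 1:
        return net
    transfer = lam * doc[..., :-1]
    net[..., :-1] -= transfer
    net[..., 1:] += transfer
    return net


def geopolymerization_rates(doc_m: np.ndarray, gps: np.ndarray,
                            lambda_gps: np.ndarray) -> np.ndarray:
    """Net rates along DOC_m → GPS_1 → … → GPS_p → lrDOC.

    Returns columns [DOC_m, GPS_1..GPS_p, lrDOC]; they sum to zero.
    """
    doc_m = np.asarray(doc_m, dtype=float)
    gps = np.asarray(gps, dtype=float)
    if gps.ndim == doc_m.ndim:  # single GPS pool passed without axis
        gps = gps[..., None]
    chain = np.concatenate([doc_m[..., None], gps], axis=-1)
    return chain_rates(chain, lambda_gps)


def sorption_exchange(cd, sd, k_sorp, kd_sorp):
    """Kinetic sorption exchange terms (bulk volumetric basis).

    dissolved term = −k_sorp C_d + (k_sorp/Kd_sorp) S_d; the sorbed term is
    its exact negation.  At the detailed-balance point ``S_d = Kd_sorp C_d``
    the net exchange vanishes.
    """
    k = np.asarray(k_sorp, dtype=float)
    kd = np.asarray(kd_sorp, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("k_sorp must be ≥0")
    if np.any((k > 0) & ~(kd > 0)):
        raise ConfigurationError("kd_sorp must be >0 where k_sorp>0")
    desorb = np.where(k > 0, k / np.where(kd > 0, kd, 1.0), 0.0)
    dissolved = -k * np.asarray(cd, dtype=float) + desorb * np.asarray(sd, dtype=float)
    return dissolved, -dissolved


def redox_partition(o2, no3, mno2, feoh3, so4, redox: RedoxConfig) -> np.ndarray:
    """Monod-with-inhibition partition of OC oxidation across the redox ladder.

    Sequential saturation: each pathway takes a Monod fraction of whatever
    the more favourable acceptors left over, so the six factors
    (O2, NO3, MnO2, FeOH3, SO4, methanogenesis) sum to exactly 1.
    Oxide concentrations are per gram dry solid; dissolved are pore-water.
    """
    def monod(c, km):
        # signed C¹ saturation: c/(km+|c|) matches Monod for c ≥ 0 and turns
        # slightly negative below zero, so undershooting concentrations see a
        # restoring (production) term instead of a residual sink
        c = np.asarray(c, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(np.abs(c) + km > 0, c / (np.abs(c) + km), np.nan)
        if np.any(~np.isfinite(f)):
            raise ConfigurationError(
                "non-finite Monod factor (zero half-saturation with zero concentration)"
            )
        return f

    fracs = np.zeros((6,) + np.shape(np.asarray(o2, dtype=float)))
    remaining = np.ones_like(np.asarray(o2, dtype=float))
    for i, (c, km) in enumerate([
        (o2, redox.km_o2), (no3, redox.km_no3), (mno2, redox.km_mno2),
        (feoh3, redox.km_feoh3), (so4, redox.km_so4),
    ]):
        f = monod(c, km) * remaining
        fracs[i] = f
        remaining = remaining - f
    fracs[5] = remaining
    return fracs


# ---------------------------------------------------------------------------
# Full network, vectorized over the column
# ---------------------------------------------------------------------------

@dataclass
class _Idx:
    """Column indices of every species in the packed state array."""

    name_to_col: dict
    poc: np.ndarray
    doc: np.ndarray
    gps: np.ndarray
    lrdoc: int
    oc_dissolved: np.ndarray  # DOC.. GPS.. lrDOC
    moc: np.ndarray  # aligned with oc_dissolved


class ReactionNetwork:
    """Evaluate all reaction terms of the model on a grid, vectorized.

    ``rates(conc)`` takes the packed concentration array (n_cells, n_species)
    in native per-phase units and returns bulk volumetric rates
    (µmol cm⁻³ bulk yr⁻¹) of identical shape.
    """

    def __init__(self, model: ModelDefinition, profiles: ColumnProfiles):
        self.model = model
        self.redox = model.redox
        names = model.species_names
        col = {nm: i for i, nm in enumerate(names)}
        self.idx = _Idx(
            name_to_col=col,
            poc=np.array([col[n] for n in model.poc_names]),
            doc=np.array([col[n] for n in model.doc_names]),
            gps=np.array([col[n] for n in model.gps_names]),
            lrdoc=col["lrDOC"],
            oc_dissolved=np.array([col[n] for n in model.dissolved_oc_names]),
            moc=np.array([col[f"MOC_{n}"] for n in model.dissolved_oc_names]),
        )
        c = col
        self.i_o2, self.i_no3, self.i_so4 = c["O2"], c["NO3"], c["SO4"]
        self.i_nh4, self.i_dic, self.i_h2s = c["NH4"], c["DIC"], c["H2S"]
        self.i_ch4, self.i_fe2, self.i_mn2 = c["CH4"], c["Fe2"], c["Mn2"]
        self.i_fhr, self.i_fmr = c["FeOH3_HR"], c["FeOH3_MR"]
        self.i_mno2, self.i_fes = c["MnO2"], c["FeS"]
        self.i_fes2, self.i_s0 = c["FeS2"], c["S0"]

        self.phi = profiles.phi_c
        self.rho_eps = model.sediment.rho_s * profiles.eps_c

        p = model.pools
        self.k_hyd = np.asarray(p.k_hyd, dtype=float)
        self.f_direct = p.f_lrdoc_direct
        self.lambda_doc = np.asarray(p.lambda_doc, dtype=float)
        self.lambda_gps = np.asarray(p.lambda_gps, dtype=float)
        self.k_remin_oc = np.concatenate([
            np.asarray(p.k_remin_doc, dtype=float),
            np.full(p.p_gps, p.k_remin_gps),
            [p.k_remin_lrdoc],
        ])
        oc_specs = [model.spec(n) for n in model.dissolved_oc_names]
        self.k_sorp = np.array([s.k_sorp for s in oc_specs])
        self.kd_sorp = np.array([s.kd_sorp for s in oc_specs])

    # -- public API ----------------------------------------------------------

    def rates(self, conc: np.ndarray, diagnostics: bool = False):
        """Bulk volumetric rates (n_cells, n_species); optionally a diagnostics dict."""
        conc = np.atleast_2d(conc)
        n_cells, _ = conc.shape
        R = np.zeros_like(conc)
        ix = self.idx
        phi, rho_eps = self.phi, self.rho_eps
        rdx = self.redox

        # --- hydrolysis: POC_i -> DOC1 (fraction f_direct straight to lrDOC)
        poc = conc[:, ix.poc]
        hyd = rho_eps[:, None] * hydrolysis_rates(poc, self.k_hyd)
        R[:, ix.poc] -= hyd
        hyd_total = hyd.sum(axis=1)
        to_lr_direct = self.f_direct * hyd_total
        R[:, ix.doc[0]] += hyd_total - to_lr_direct
        R[:, ix.lrdoc] += to_lr_direct

        # --- sequential DOC cascade (bulk, as printed in the governing eqs)
        doc = conc[:, ix.doc]
        R[:, ix.doc] += cascade_rates(doc, self.lambda_doc)

        # --- geopolymerization chain DOC_m -> GPS... -> lrDOC
        chain_conc = np.concatenate(
            [doc[:, -1:], conc[:, ix.gps], conc[:, [ix.lrdoc]]], axis=1
        )
        gps_in = self.lambda_gps[0] * chain_conc[:, 0]
        chain_net = chain_rates(chain_conc[:, :-1], self.lambda_gps)
        gps_to_lr = self.lambda_gps[-1] * chain_conc[:, -2]
        R[:, ix.doc[-1]] += chain_net[:, 0]
        R[:, ix.gps] += chain_net[:, 1:-1]
        R[:, ix.lrdoc] += chain_net[:, -1]

        # --- remineralization across the redox ladder
        delta_fe = 1e-6 * rdx.km_feoh3 if rdx.km_feoh3 > 0 else 1e-6
        fhr_pos = _softpos(conc[:, self.i_fhr], delta_fe)
        fmr_pos = _softpos(conc[:, self.i_fmr], delta_fe)
        feoh3_reactive = conc[:, self.i_fhr] + conc[:, self.i_fmr]
        fracs = redox_partition(
            conc[:, self.i_o2], conc[:, self.i_no3], conc[:, self.i_mno2],
            feoh3_reactive, conc[:, self.i_so4], rdx,
        )  # (6, n_cells)
        ox_pool = phi[:, None] * self.k_remin_oc * conc[:, ix.oc_dissolved]
        ox_total = ox_pool.sum(axis=1)
        R[:, ix.oc_dissolved] -= ox_pool
        ox_path = fracs * ox_total  # (6, n_cells)
        # carbon: everything to DIC except methanogenesis, which splits 50/50
        R[:, self.i_dic] += ox_total - ox_path[5] + 0.5 * ox_path[5]
        R[:, self.i_ch4] += 0.5 * ox_path[5]
        # electron acceptors / reduced products
        R[:, self.i_o2] -= 1.0 * ox_path[0]
        R[:, self.i_no3] -= 0.8 * ox_path[1]
        R[:, self.i_mno2] -= 2.0 * ox_path[2]
        R[:, self.i_mn2] += 2.0 * ox_path[2]
        w_hr = fhr_pos / np.maximum(fhr_pos + fmr_pos, 1e-300)
        R[:, self.i_fhr] -= 4.0 * ox_path[3] * w_hr
        R[:, self.i_fmr] -= 4.0 * ox_path[3] * (1.0 - w_hr)
        R[:, self.i_fe2] += 4.0 * ox_path[3]
        R[:, self.i_so4] -= 0.5 * ox_path[4]
        R[:, self.i_h2s] += 0.5 * ox_path[4]
        R[:, self.i_nh4] += ox_total / rdx.cn_ratio

        # --- kinetic sorption exchange with the MOC pools
        cd = conc[:, ix.oc_dissolved]
        sd = conc[:, ix.moc]
        net_sorp = self.k_sorp * cd - (self.k_sorp / self.kd_sorp) * sd
        R[:, ix.oc_dissolved] -= net_sorp
        R[:, ix.moc] += net_sorp

        # --- secondary redox network
        sec = self._secondary(conc)
        R += sec

        if not diagnostics:
            return R

        diag = {
            "hydrolysis_total": hyd_total,
            "hydrolysis_to_doc1": hyd_total - to_lr_direct,
            "hydrolysis_to_lrdoc": to_lr_direct,
            "geopoly_influx": gps_in,
            "gps_to_lrdoc": gps_to_lr,
            "lrdoc_direct": to_lr_direct,
            "remin_total": ox_total,
            "remin_pathways": ox_path,
            "remin_per_pool": ox_pool,
            "net_sorption": net_sorp,
            "sorption_gross": self.k_sorp * cd,
            "desorption_gross": (self.k_sorp / self.kd_sorp) * sd,
        }
        return R, diag

    # -- secondary redox -----------------------------------------------------

    def _secondary(self, conc: np.ndarray) -> np.ndarray:
        """Bimolecular Fe/Mn/S/CH4 sub-network; each reaction conserves its element."""
        rdx = self.redox
        phi, rho_eps = self.phi, self.rho_eps
        R = np.zeros_like(conc)

        # Bimolecular terms use gated raw products: exact mass action while
        # either reactant is positive (linear restoring for transient
        # negatives), smoothly zero when both are negative (the self-
        # amplifying configuration).  First-order terms are plain linear.
        DD, DS = 1e-6, 1e-3  # gate widths: dissolved µmol cm⁻³, solid µmol g⁻¹

        def cc(i):
            return conc[:, i]

        o2, so4 = cc(self.i_o2), cc(self.i_so4)
        h2s, fe2, mn2, ch4 = cc(self.i_h2s), cc(self.i_fe2), cc(self.i_mn2), cc(self.i_ch4)
        fes, s0 = cc(self.i_fes), cc(self.i_s0)
        fhr, mno2 = cc(self.i_fhr), cc(self.i_mno2)

        # Fe2 + 0.25 O2 -> FeOH3_HR
        r = phi * rdx.k_fe_ox * _gated_product(fe2, o2, DD, DD)
        R[:, self.i_fe2] -= r
        R[:, self.i_o2] -= 0.25 * r
        R[:, self.i_fhr] += r
        # Mn2 + 0.5 O2 -> MnO2
        r = phi * rdx.k_mn_ox * _gated_product(mn2, o2, DD, DD)
        R[:, self.i_mn2] -= r
        R[:, self.i_o2] -= 0.5 * r
        R[:, self.i_mno2] += r
        # H2S + 2 O2 -> SO4
        r = phi * rdx.k_h2s_ox * _gated_product(h2s, o2, DD, DD)
        R[:, self.i_h2s] -= r
        R[:, self.i_o2] -= 2.0 * r
        R[:, self.i_so4] += r
        # CH4 + 2 O2 -> DIC
        r = phi * rdx.k_ch4_ox * _gated_product(ch4, o2, DD, DD)
        R[:, self.i_ch4] -= r
        R[:, self.i_o2] -= 2.0 * r
        R[:, self.i_dic] += r
        # CH4 + SO4 -> DIC + H2S (anaerobic oxidation of methane)
        r = phi * rdx.k_aom * _gated_product(ch4, so4, DD, DD)
        R[:, self.i_ch4] -= r
        R[:, self.i_so4] -= r
        R[:, self.i_dic] += r
        R[:, self.i_h2s] += r
        # Fe2 + H2S -> FeS
        r = phi * rdx.k_fes_ppt * _gated_product(fe2, h2s, DD, DD)
        R[:, self.i_fe2] -= r
        R[:, self.i_h2s] -= r
        R[:, self.i_fes] += r
        # FeS -> Fe2 + H2S
        r = rho_eps * rdx.k_fes_diss * fes
        R[:, self.i_fes] -= r
        R[:, self.i_fe2] += r
        R[:, self.i_h2s] += r
        # FeS + S0 -> FeS2
        r = rho_eps * rdx.k_fes2 * _gated_product(fes, s0, DS, DS)
        R[:, self.i_fes] -= r
        R[:, self.i_s0] -= r
        R[:, self.i_fes2] += r
        # 4 S0 -> 3 H2S + SO4 (disproportionation; per S0 consumed)
        r = rho_eps * rdx.k_s0_disp * s0
        R[:, self.i_s0] -= r
        R[:, self.i_h2s] += 0.75 * r
        R[:, self.i_so4] += 0.25 * r
        # H2S + 2 FeOH3_HR -> S0 + 2 Fe2
        r = rdx.k_h2s_feoh3 * rho_eps * _gated_product(fhr, h2s, DS, DD)
        R[:, self.i_h2s] -= r
        R[:, self.i_fhr] -= 2.0 * r
        R[:, self.i_s0] += r
        R[:, self.i_fe2] += 2.0 * r
        # H2S + MnO2 -> S0 + Mn2
        r = rdx.k_h2s_mno2 * rho_eps * _gated_product(mno2, h2s, DS, DD)
        R[:, self.i_h2s] -= r
        R[:, self.i_mno2] -= r
        R[:, self.i_s0] += r
        R[:, self.i_mn2] += r
        return R

    # -- audit export ---------------------------------------------------------

    def network_table(self) -> pd.DataFrame:
        """Reaction inventory (reaction, rate law, constant) for audit."""
        rdx = self.redox
        rows = [
            ("hydrolysis", "POC_i -> DOC1 (+ f_direct to lrDOC)", "k_i * C_POCi", "per-pool"),
            ("cascade", "DOC_i -> DOC_i+1", "lambda_DOC * C", f"{self.lambda_doc.tolist()}"),
            ("geopolymerization", "DOC_m -> GPS.. -> lrDOC", "lambda_GPS * C", f"{self.lambda_gps.tolist()}"),
            ("remineralization", "OC + EA -> DIC (ladder)", "phi k_remin C * Monod", f"{self.k_remin_oc.tolist()}"),
            ("kinetic_sorption", "DOC <-> MOC", "k_sorp C - (k_sorp/Kd_sorp) S", f"{self.k_sorp.tolist()}"),
            ("fe_oxidation", "Fe2 + 0.25 O2 -> FeOH3_HR", "phi k [Fe2][O2]", rdx.k_fe_ox),
            ("mn_oxidation", "Mn2 + 0.5 O2 -> MnO2", "phi k [Mn2][O2]", rdx.k_mn_ox),
            ("h2s_oxidation", "H2S + 2 O2 -> SO4", "phi k [H2S][O2]", rdx.k_h2s_ox),
            ("ch4_oxidation", "CH4 + 2 O2 -> DIC", "phi k [CH4][O2]", rdx.k_ch4_ox),
            ("aom", "CH4 + SO4 -> DIC + H2S", "phi k [CH4][SO4]", rdx.k_aom),
            ("fes_precipitation", "Fe2 + H2S -> FeS", "phi k [Fe2][H2S]", rdx.k_fes_ppt),
            ("fes_dissolution", "FeS -> Fe2 + H2S", "rho_s eps k [FeS]", rdx.k_fes_diss),
            ("fes2_formation", "FeS + S0 -> FeS2", "rho_s eps k [FeS][S0]", rdx.k_fes2),
            ("s0_disproportionation", "4 S0 -> 3 H2S + SO4", "rho_s eps k [S0]", rdx.k_s0_disp),
            ("h2s_feoh3", "H2S + 2 FeOH3_HR -> S0 + 2 Fe2", "k rho_s eps [FeOH3][H2S]", rdx.k_h2s_feoh3),
            ("h2s_mno2", "H2S + MnO2 -> S0 + Mn2", "k rho_s eps [MnO2][H2S]", rdx.k_h2s_mno2),
        ]
        return pd.DataFrame(rows, columns=["reaction", "stoichiometry", "rate_law", "constants"])

    def carbon_columns(self) -> np.ndarray:
        """Packed-state columns that carry carbon (OC pools + DIC + CH4)."""
        ix = self.idx
        return np.concatenate([
            ix.poc, ix.oc_dissolved, ix.moc, [self.i_dic, self.i_ch4]
        ])
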