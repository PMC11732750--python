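# Methods

## The model

`sedmoc` solves a vertically resolved early-diagenesis reaction-transport
model for organic carbon (OC) in marine sediments, built around the idea
that dissolved organic carbon (DOC) — not only particulate OC (POC) — sets
how much carbon survives burial. Three phases are tracked on a 1-D column
(z = 0 at the sediment–water interface, positive downward):

* **dissolved** species (µmol cm⁻³ pore water): O₂, NO₃, SO₄, NH₄, DIC,
  H₂S, CH₄, Fe²⁺, Mn²⁺ plus the organic pools DOC₁..DOC_m (a cascade of
  decreasing molecular weight and increasing reactivity), GPS₁..GPS_p
  (geopolymerized substances) and lrDOC (least-reactive DOC);
* **particulate** species (µmol g⁻¹ dry solid): POC₁..POC_n reactivity
  pools, three Fe-oxide phases, MnO₂, FeS, FeS₂, S⁰;
* **sorbed** species (µmol g⁻¹ dry solid): one mineral-phase OC (MOC) pool
  per dissolved OC pool, created by net kinetic sorption.

The dissolved balance combines molecular diffusion (tortuosity-corrected,
θ² = 1 − 2 ln φ), bioturbation of the equilibrium-adsorbed fraction
(mixed diffusivity φD + ρ_s ε K_d D_b and mixed advection
φv_d + ρ_s ε K_d v_p), nonlocal bio-irrigation exchange φα(C(0) − C(z)),
reactions, and linear kinetic exchange with the partner MOC pool,
−k_sorp C_d + (k_sorp/Kd_sorp) S_d. Particulate and sorbed species are
mixed by bioturbation (ρ_s ε D_b) and buried (ρ_s ε v_p); MOC is
chemically inert unless carbon desorbs. The kinetic exchange terms carry
no porosity prefactor — they are bulk-volume rates — which makes the
dissolved and sorbed equations mutually conservative by construction.

Carbon routing: POC pools hydrolyse at first order (multi-G) into DOC₁,
with a fraction `f_lrdoc_direct` of the freshly produced carbon routed
straight to lrDOC (intrinsically undegradable material). The cascade
DOC_i → DOC_{i+1} (rates λ) raises reactivity step by step;
DOC_m → GPS₁ → GPS₂ → lrDOC represents geopolymerization to progressively
less reactive high-molecular-weight material. Every dissolved OC pool is
remineralized at first order, partitioned across the redox ladder
(O₂ > NO₃ > MnO₂ > Fe-oxide > SO₄ > methanogenesis) with sequential
Monod-with-inhibition factors that sum to exactly one; DIC receives the
oxidized carbon 1:1 (half to CH₄ under methanogenesis) and NH₄ is released
at Redfield C:N. A compact Fe/Mn/S/CH₄ secondary network (iron and
manganese oxidation, sulfide oxidation by O₂/oxides, FeS precipitation and
dissolution, pyrite formation via FeS + S⁰, S⁰ disproportionation, aerobic
and anaerobic methane oxidation) closes the element cycles; its rate forms
are Van Cappellen-style bimolecular mass action with all constants exposed
in config.

Reactivity classes are specified by lifetime: the (semi)labile cascade
spans 9 h to 1.5 yr (log-spaced across the m pools), GPS ~20 yr, lrDOC
~16,000 yr. POC reactivity comes from a gamma reactive continuum (age
parameter `a`, shape `nu`) discretized into n log-spaced bins of the
dimensionless rate u = a·k; each pool carries the bin's gamma mass at the
bin's geometric midpoint rate. Binning in u makes the scaling exact
(doubling `a` halves every rate constant) and keeps the pooled decay
within ~2 % of the closed-form continuum survival (a/(a+t))^ν over
1–1000 yr.

## Preservation efficiency

At a depth horizon L (default 1 m):

* conventional PE (burial efficiency):
  `PE_POC = 100 · F_POC(L) / F_POC(0)`,
  with F_POC the advective + bioturbative POC flux;
* redefined PE:
  `PE = 100 · (F_POC(L) + ∫₀ᴸ net kinetic sorption dz) / F_POC(0)`,
  where net kinetic sorption (gross sorption minus desorption, i.e. the
  net MOC formation rate) credits carbon captured on minerals above the
  horizon.

With all `k_sorp = 0` the integral is identically zero and the two forms
coincide exactly. Fluxes are evaluated at cell faces with the same scheme
as the transport operator — consistency over formal accuracy — so the
discrete divergence theorem holds to round-off (the flux lost between two
faces equals the integrated source between them).

Mass budgets are reported as carbon throughflow at three redundant
cross-sections (supply: POC + dissolved OC + MOC influx + irrigation
delivery; hydrolysis split: hydrolysed carbon + unhydrolysed burial +
pass-through; fate: remineralization + burial of all OC phases). At steady
state the three agree to the solver tolerance; the converged canonical
column closes to <1e-4 %, far inside the 1 % acceptance bound.

## Numerics

Finite volumes on a geometrically stretched grid (first cell ≤ 0.1 cm at
the interface, default 500 cm domain). Face fluxes use Patankar's
power-law advection–diffusion weighting (pure upwind available), so the
column sum of the operator action telescopes exactly to the net boundary
flux; a closed column conserves mass to machine precision. Dirichlet
concentrations at the interface for all phases (MOC defaults to zero —
it is formed in the sediment), zero-diffusive-gradient with advective
outflow at the base.

Steady states are found by pseudo-transient continuation (PTC): implicit
Euler steps (accfac/Δτ − J)δ = F(y), where J exploits the problem's
structure — transport is a constant sparse matrix and reactions are local
to each cell, so S finite-difference perturbations (one per species,
applied to all cells at once) yield the exact sparse Jacobian — with
switched evolution relaxation of Δτ, and — once
Δτ is large and the step is effectively Newton's — a monotone line search
that suppresses the limit cycles sharp redox fronts otherwise provoke.
The iteration starts from a profile-shaped guess (multi-G decay of POC at
the burial velocity, exponentially attenuated oxides, shallow O₂/NO₃
penetration). If PTC stalls, a homotopy solves the column with the
secondary-redox constants weakened 100-fold and continues to full
strength; remaining cases fall back to stiff BDF integration with a
damped-Newton polish. Convergence is the maximum over species of the
relative L2 norm of dC/dt below 1e-8 yr⁻¹ (configurable). Ensemble draws
use a fast profile that skips the BDF fallback; draws that still fail are
flagged, excluded from aggregates and counted — never resampled, which
would bias the parameter distribution.

Rate laws are kept C¹ smooth for Newton's sake, and every term gives a
transiently negative concentration a *restoring* force rather than a
residual sink:

* first-order terms are plain linear in the raw concentration;
* Monod factors use the signed saturation `c/(K_m + |c|)`, which matches
  Monod exactly for c ≥ 0 and turns slightly negative below zero;
* bimolecular terms use the raw product `a·b` multiplied by a smooth gate
  that switches the rate off only in the double-negative quadrant, where
  a raw product would self-amplify (both reactants driven ever more
  negative by their own "production"); wherever either reactant is
  positive the mass-action law is exact.

Hard `max(c, 0)` clipping was rejected — it makes the steady-state
problem non-smooth and the Newton iteration limit-cycles instead of
converging — and softplus-floored reactants were rejected too, because
the floor times a large partner concentration creates phantom rates that
push trace species (S⁰, oxides) persistently negative. With the gated
formulation, steady-state undershoots are bounded by the solver tolerance
at ~1e-7..1e-6 of each species' scale; output clipping zeroes negatives
within 1e-5 relative, and anything larger would signal a solver failure
and is left visible.

## The ensemble stage and what it emulates

`run_ensemble` samples a flat table of parameter distributions (name =
dot-path into the config, family, two parameters, hard truncation bounds,
process tag, emulator transform), solves the column per draw, and records
per-draw scalars (conventional and redefined PE, POC fluxes, net sorption,
MOC formation split by pool class) plus depth profiles (PE vs depth,
sorption/desorption ratio, GPS share of lrDOC production, cumulative MOC
formation) aggregated as means with percentile 95 % bands. Determinism:
(seed, table, solver options) fully determine the result.

The shipped table is an editable approximation of a global exercise. Five
"gridded" inputs follow truncated normals/lognormals — sediment
accumulation rate (lognormal, median 0.03 cm yr⁻¹, σ_ln 1.2, truncated to
0.002–1: global compilations put most of the seafloor at 0.001–0.1 with
shelves up to ~1), surface porosity (normal 0.85 ± 0.05), SWI total OC
(lognormal median 1.5 wt%), bottom-water O₂ (lognormal median 150 µM,
down to suboxic) and NO₃. The remaining 22 kinetic/transport parameters
are loguniform over literature-style ranges: continuum age 0.1–30 yr,
cascade conversion 1–100 yr⁻¹, direct-to-lrDOC fraction 0.01–0.2,
bioturbation 0.3–50 cm² yr⁻¹, irrigation 0.3–30 yr⁻¹, equilibrium K_d
1–100 cm³ g⁻¹, kinetic k_sorp 0.1–30 yr⁻¹ and Kd_sorp 10²–10⁴ cm³ g⁻¹
(the wide spans reflect how poorly constrained sorption kinetics are),
geopolymerization influx 3–300 yr⁻¹ and chain conversion 0.01–1 yr⁻¹.
Every parameter maps to exactly one of six processes (DOC hydrolysis,
remineralization, mixing, equilibrium adsorption, kinetic sorption,
geopolymerization) for the importance stage.

What the generator does **not** emulate: real spatial covariance between
inputs (depth–flux–O₂ correlations are ignored; parameters are sampled
independently), carbonate chemistry, temperature dependence of rate
constants, transient seasonal forcing, and age-dependent (as opposed to
depth-dependent) preservation horizons. Passing ensemble checks therefore
demonstrates internal consistency of the machinery under plausible global
ranges, not agreement with any specific field site.

## ANN process importance

A three-layer network (standardized inputs — log first where the table
says so — a tanh hidden layer sized by held-out Nash–Sutcliffe efficiency
at roughly ≥10 rows per neuron, linear output) emulates each scalar
output. Sensitivity of an input is the mean absolute partial derivative
of the emulated output over the sample, computed analytically by the
chain rule (W₁ · diag(1 − h²) · w₂; for a single linear neuron this
reduces to the weight itself). A process's raw score is the **maximum**
over its member parameters; scores are normalized to 100 %. Confidence
intervals come from repeated trainings with fresh weight initialization
and bootstrap-resampled rows (both randomization sources are standard;
the hidden width is selected once and held fixed across repeats). The
network is used only for importance analysis, never for prediction.

## Problem sizes

Default single-column runs use 45–100 cells (the canonical validation runs
use 60, the equivalence pair 45); ensemble draws use 32 cells, and the
scaled ensemble in the test suite runs 200 draws. These sizes keep the
full validation suite in minutes while the grid-refinement tests confirm
the transport discretization converges at first order or better.

## Known limitations

* The equivalence of kinetic sorption at high exchange rate with
  equilibrium adsorption holds exactly only when the SWI dissolved-OC
  concentrations are zero; otherwise the kinetic run's MOC = 0 interface
  condition cannot match the equilibrium sorbed load K_d·C(0). The
  shipped equivalence fixture therefore generates all dissolved OC within
  the sediment.
* A few percent of ensemble draws (typically high-OC, low-O₂ corners) do
  not reach the 1e-8 steady-state tolerance within the fast-solver budget
  and are excluded as failures.
* Secondary-redox rate constants are order-of-magnitude literature values;
  FeS₂ and Mn²⁺ chemistry in particular is simplified (no carbonate
  system).
* The bio-irrigation coefficient α is implemented as a nonlocal exchange
  rate (yr⁻¹) multiplying φ(C(0) − C(z)); treatments that print α in
  cm² yr⁻¹ are dimensionally inconsistent with that exchange form.
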