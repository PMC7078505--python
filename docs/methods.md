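# Methods

## Scope and model structure

`nanopbpk` simulates the whole-body disposition of intravenously injected
nanoparticles (NPs) in a reference 200 g rat, with a facultative spherical
tumor. The model is a linear, time-invariant compartmental ODE system whose
state is the NP *amount* (%ID, percent of injected dose) in each
sub-compartment. Compartments: a well-mixed venous plasma pool; nine organs
(lungs, liver, kidneys, spleen, brain, heart, GI tract, muscle, a lumped
"others"), each split into free-vascular, bound-vascular and extravascular
sub-compartments, with an additional phagocytic sub-compartment in the MPS
organs (liver, spleen); a lymph-node pool; the tumor (free/bound vascular
plus interstitium); and three absorbing pools (urine, feces, degraded).

The distinguishing feature is that the rate constants coupling particles to
the microvascular wall are computed mechanistically from NP design
parameters (radius r, density ρ_np, degradation rate k_deg) and organ-level
physiology, not fitted:

- **Wall deposition** k_on = v·D·l/(u·R³), where v = (2/9)·((ρ_np−ρ_p)/μ)·g·r²
  is the Stokes terminal sedimentation velocity, divided by the advective
  Peclet number u·R²/(D·l) and the margination length R. The effective
  diffusivity D = D_B + D_S combines Stokes–Einstein Brownian motion
  D_B = k_B·T/(6πμr) and erythrocyte shear-induced dispersion
  D_S = 0.3·β²·γ̇·H².
- **Wall dislodging** k_off = D_B/l_g², diffusive escape over the glycocalyx
  thickness l_g.
- **Phagocytosis** k_mac = p/(4πr²γ), the inverse membrane wrapping time set
  by motor-protein power p against membrane tension γ; the flux into the
  phagocytic pool is scaled by the macrophage wall coverage A_mac (0.5
  liver, 0.1 spleen, 0 elsewhere).
- **Transvascular bulk transport** is hindered by the osmotic reflection
  coefficient σ(α) = 1 − {[1−(1−(1−α)²)²]·G + (16/9)α²(1−α)²·F}, α = r/r_pore.
- **Tumor extravasation** is purely diffusive through the leaky wall:
  P = φ·(1−α_T)·F(α_T)·D_B/l_w, with D_B evaluated at the tumor blood
  viscosity (7.42 cP); the exchange coefficient is the permeability–surface
  product P·S.

### Hindrance closures

The pore-hindrance pair (F, G) is pluggable. Defaults are the classical
centerline approximations: the Renkin polynomial
F(α) = (1−α)²(1 − 2.104α + 2.09α³ − 0.95α⁵) for diffusion, and the
Anderson–Quinn lag coefficient
G(α) = (1 − (2/3)α² − 0.20217α⁵)/(1 − 0.75857α⁵) for convection. Both are
clamped to [0, 1] and set to zero for α ≥ 1. With these defaults σ(α) is
continuous and non-decreasing on [0, 1] (verified numerically on a 2·10⁵
point grid) and the tumor permeability values reproduce the reference
figures at 90 nm and 9.4 nm size within 7% and 1% respectively. Published
tabulations of healthy-organ σ at 10 nm reference size differ for the liver
(large 140 nm fenestrae); no standard closure reproduces that entry, and it
is not treated as a constraint.

"Size" in all user-facing interfaces is the hydrodynamic **diameter** (2r);
the rate laws are written in r. This convention is forced by the printed
permeability reference values, which are reproduced only with r = size/2.

## Circulatory topology

The reference equations define the organ sub-compartments; the closing
balances (plasma, lungs, lymph node, excretion) are standard PBPK anatomy:

- Plasma feeds the lungs with the entire cardiac output (CO = 4217 ml/h);
  the post-lung arterial stream perfuses the parallel organs at their
  fractional cardiac outputs, and the unallocated remainder (≈ 0.326·CO)
  shunts back to plasma.
- GI and spleen drain through the liver (portal vein); the liver's total
  inflow is the hepatic-artery share (0.021·CO) plus those portal streams.
- Lymph flow is 1/500 of plasma flow per organ. Extravascular spaces drain
  to a lymph-node pool (volume 0.002·BW, configurable — it only sets a
  small transit delay) that returns to plasma.
- Kidney: glomerular filtration moves free vascular NPs to the tubular
  (extravascular) space at GFR·(1−σ_K); urine outflow (U = 2.0833 ml/h)
  feeds an absorbing urine pool. Because the kidney pore radius is 4 nm,
  particles of diameter ≥ 8 nm have σ_K = 1 and are never filtered — the
  renal size cutoff.
- Liver: bile (B = 0.9375 ml/h) carries extravascular NPs to an absorbing
  feces pool; GI transit is lumped out since only the cumulative excreted
  amount is tracked.
- Degradation (first order, k_deg) acts only on phagocytized NPs and on the
  tumor interstitium, feeding an explicit "degraded" pool that is counted
  with the excreta.
- The tumor exchanges blood directly with plasma at Q_T = specific flow ×
  tumor mass, has zero lymph flow (compressed lymphatics), no phagocytic
  sub-compartment, and one-way diffusive influx P·S·C_v,T into its
  interstitium.

Two topology details were genuinely open: whether lung venous return passes
through plasma (the implemented series plasma → lungs → organs reading) and
whether lymph-node effluent re-enters plasma directly (implemented) or via
the lungs. Neither choice is observable in the reported outputs at the
achieved tolerances.

## Tumor geometry and microcirculation

The tumor is a sphere (default radius 5 mm, unit tissue density). Its
microvascular surface-area density uses the cylinder lateral-area rule
s = 2·f_v,T/R = 40 mm²·mm⁻³ at the defaults, and total surface
S = s·V_T ≈ 2.09·10⁴ mm². The capillary count partitions the capillary
share (f_cap = 0.55) of the tumor vascular volume into vessels of radius
5 μm and length 1 mm (N ≈ 3.7·10⁵); dividing the bulk perfusion
(0.1 ml·g⁻¹·min⁻¹) over those vessels gives per-capillary flow
≈ 0.14 nl·min⁻¹, mean velocity ≈ 30 μm·s⁻¹, and Poiseuille mean shear
γ̇ = (8/3)u/R ≈ 16 s⁻¹ — all inside the reported ranges for tumor
microcirculation. Healthy-organ capillary hemodynamics (u = 553 μm·s⁻¹,
γ̇ = 116 s⁻¹, Q_cap = 2.58 nl·min⁻¹) are fixed configurable constants; they
are not derivable from the organ tables by the same partition (the implied
per-capillary flow is ~2.2× smaller), and the tumor derivation is the one
the reference values constrain.

## Numerics

- State is stored as amounts so that every elementary transfer appears as a
  matched source/sink pair; the system matrix has exactly zero column sums
  and mass conservation holds by construction (observed drift ≤ 1e-10 %ID
  over 1000 h).
- The system is stiff: glycocalyx dislodging (~4·10⁵ h⁻¹) versus terminal
  elimination (~10⁻² h⁻¹). Integration uses SciPy's BDF with the exact
  constant Jacobian, rtol 1e-8 / atol 1e-10 by default.
- The output grid is t = 0 plus 500 log-spaced points on [10⁻³ h, t_end];
  AUCs use the composite trapezoid on that grid (≤ 0.02% error on
  exponential-like trajectories). "AUC₀₋∞" is operationalized as AUC over
  [0, 1000 h].
- k_mac diverges as r → 0; it is clamped at 10⁴ s⁻¹ (never binding for
  r ≥ 1 nm at the default p, γ, but protective in parameter scans).
  Buoyant particles (ρ_np < ρ_p) would give a negative deposition rate;
  k_on is clamped at zero (sedimentation-driven deposition is one-sided).
- Degenerate inputs: α ≥ 1 forces σ = 1 and P = 0 exactly; φ = 0 gives
  P·S = 0 (no extravasation); disabling the tumor removes its states
  entirely.

## Sensitivity analysis

Eleven parameters are analyzed (NP: r, ρ_np, k_deg; tumor: Q_T, μ_T, f_v,T,
r_pore,T, φ; individual: A_mac,L, A_mac,S, H), each perturbed uniformly
within ±99% of its reference value; outputs are the AUCs of plasma, MPS
(liver + spleen, all sub-compartments), tumor interstitium, and total
excreta.

- **LSA**: one-at-a-time scans (default 1000 equally spaced levels,
  excluding the reference point) scored by the normalized sensitivity
  coefficient SC = relative AUC change / relative parameter change, ranked
  per output by max |SC|; ties break by declared parameter order, and
  outputs with zero reference AUC are flagged and excluded.
- **GSA**: Latin hypercube designs (default 5000 × 10 replicates; one
  sample per stratum per column, independently permuted; replicate
  substreams spawned from a master seed). Three techniques per replicate:
  standardized multiple linear regression (|β|), partial rank correlation
  (|PRCC|, rank-transform then residual correlation controlling for the
  other ten parameters), and one-way ANOVA F across equal-count quartile
  bins (binning choice is configurable; quartiles give a balanced one-way
  design). Per technique, parameters are ordered by mean |SI| across
  replicates with Tukey-HSD grouping (α = 0.05) assigning tied ranks to
  statistically indistinguishable parameters; the consensus rank is the
  re-ranked equal-weight average of the three technique ranks (no weighting
  scheme is privileged; weights are exposed implicitly through the rank
  table). MLRA coefficients are standardized because raw coefficients are
  scale-dependent and unusable as indices; mean (not median) |SI|
  aggregates replicates.

At reduced sampling scale (n = 200, 2 replicates) the tumor-related
parameters are statistically indistinguishable from inert for the systemic
outputs (plasma, MPS, excreta) — the tumor is < 0.3% of body mass — while
the degradation rate occupies the top excretion rank, jointly with NP
radius when the replicate count is too small for Tukey to separate them.

## Delivery-efficiency window

Delivery efficiency is the tumor-interstitium AUC over [0, t] divided by t
(t = 1000 h). At the reference parameterization the efficiency-versus-
diameter curve peaks near 13 nm, exceeds 0.7 %ID only within roughly
7–20 nm, and declines monotonically above the peak. Below the 8 nm renal
cutoff the curve is *not* monotone: shrinking the particle simultaneously
accelerates renal clearance (σ_K falls) and raises the diffusive tumor
permeability (D_B ∝ 1/r), leaving a shallow local extremum near 1–3 nm
while efficiency stays far below the 0.7 %ID threshold. This boundary
structure is a genuine consequence of the rate laws (it persists at
rtol = 1e-11), not a solver artifact.

## Synthetic biodistribution fixture

The validation workflow correlates model predictions against organ
concentration time courses (%ID·g⁻¹). No third-party in vivo dataset is
bundled; `nanopbpk.fixtures.generate_fixture` produces a synthetic stand-in
with the same structure: the tumor-free model is simulated, organ totals
(all sub-compartments summed, since imaging cannot distinguish them) are
divided by organ mass (f_WT·BW at unit density), and per-animal
multiplicative lognormal noise with a chosen CV (default 0.2, n = 4
replicates, schedule {0.5, 1, 2, 4, 8, 24} h) is applied mean-preservingly.
Passing correlation tests against this fixture demonstrates that the
workflow is wired correctly and robust to realistic measurement noise; it
does **not** validate the model against real animals — the fixture inherits
the model's own kinetics, contains no inter-animal physiological
variability, no organ-specific bias, and no detection limits. Users supply
real observations as a CSV (organ, time_h, mean_percent_id_per_g, sd, n)
to run the genuine validation.

## Problem sizes used in the shipped checks

The test suite runs the full model at the reference output grid
(501 points) for single simulations, a 50-point diameter scan for the
delivery-efficiency window, a 9-level LSA and an n = 200 × 2-replicate GSA
for the ranking properties; these sizes were chosen as the smallest at
which the qualitative conclusions are stable under the fixed seeds. The
library defaults (1000 LSA levels, 5000 × 10 LHS) match the reference
workflow and are what the CLI uses unless overridden.

## Known limitations

- No ligand–receptor targeting, surface-charge effects, protein-corona
  kinetics, or drug release/pharmacodynamics.
- The tumor is spatially homogeneous; no intratumoral gradients.
- Bound tumor NPs have no loss channel other than dislodging, and the
  interstitial influx is one-way — both taken literally from the model
  equations, which makes long-horizon tumor retention optimistic for very
  permeable walls.
- Physiology is a fixed reference rat; no inter-species or inter-individual
  scaling.
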