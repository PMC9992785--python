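# Methods

## The model

Substrate cohesion is cast as an energy budget at the sediment–water
interface. Interfacial free energy G_int = σA is stored at mineral–fluid
contacts; cementation destroys surface area (dE_chem/dt < 0 contribution),
while grain impacts during transport and the mechanical work of burrowers
create it. The signed balance

dG_int/dt = dE_sed/dt + dE_bio/dt − dE_chem/dt

is the package's central quantity: negative values mean cements can
accumulate into cohesive substrates, positive values mean physical energy
keeps the bed loose. All fluxes are normalised per unit seafloor area per
year. The year is the canonical time unit because the precipitation rate
constant is calibrated per year; hydraulic submodels compute in seconds and
convert only at the flux boundary (a deliberate guard against silent
3×10⁷-fold unit errors).

The framework treats the three fluxes as independent. It does not couple
bioirrigation to porewater chemistry (burrowers in reality lower Ω by
ventilating sediments), does not track time-dependent cementation
trajectories in the headline numbers, and compares *rates*, not integrated
histories.

## Chemical flux

The cementation flux chains four pieces:

1. **Specific surface area** A_sp = r_f/(ρ_c D): surface-to-volume of a
   grain scales as 1/D; the roughness factor r_f = 5 accounts for
   microscale texture. The literature geometric model can also be read as
   carrying the sphere's factor 6; the implementation follows the bare
   inverse-diameter form and exposes `sphere_factor` for the alternative.
2. **Rate law** k(Ω−1)ⁿ with aragonite constants k = 0.113 mol m⁻² yr⁻¹,
   n = 2.26 (the k unit is read as per-area, mol m⁻² yr⁻¹ — the only
   reading under which the precipitation equation is dimensionally
   closed).
3. **Surface–porosity closure** A = A₀(φ/φ₀)^(2/3), giving
   dA/dt = −(2/3)(A₀²/(φ₀V_t))[(V_t−V_c)/(V_t−V_c₀)]^(1/3)(M_c/ρ_c)k(Ω−1)ⁿ.
   The bracketed attenuation is 1 at the onset of cementation and → 0 as
   pores fill. The headline flux reports the onset (maximum-rate) case;
   `surface_area_rate` exposes the full expression for evolution studies.
4. **Vertical window** L = 0.05 m, the median burrow depth, converting the
   volume-normalised rate into an area-normalised one.

Dissolution (Ω < 1) is a domain error, not a negative flux: the rate law is
precipitation-only. A note on sensitivity: between Ω = 3 (modern tropical
surface seawater) and Ω = 10 (anoxic porewaters / early Phanerozoic
scenarios) the rate law gives a factor (9/2)^2.26 ≈ 29.9 — about 1.5 orders
of magnitude, somewhat more than the "approximately one order" sometimes
quoted for this contrast; the package reports the computed rate-law value.

## Transport flux

dE_sed/dt = ½A₁ρ_c q w_i³/(UHχ + U_bH_b) is the energy-transfer truncation
of a total-load abrasion model. The printed equation multiplies q by ρ_c,
so q must be the *volumetric* supply per unit flow width [m² s⁻¹]; the
package treats it so. The headline equation fixes none of its inputs, so
each submodel is an explicit, configurable choice with a literature-standard
default:

* settling velocity: Ferguson–Church explicit form (C₁ = 18, C₂ = 1);
* threshold of motion: Brownlie's explicit fit of the Shields curve
  (constant τ*c available via config);
* bedload layer: H_b = 1.44D(τ*/τ*c)^0.5 (capped at H),
  U_b = 1.56√(R′gD)(τ*/τ*c)^0.56 — transport-stage power laws from the
  total-load erosion literature;
* suspension integral: χ = (1/UH)∫u(z)ĉ(z)dz from H_b to H with the
  log-law u(z) = (u*/κ)ln(z/z0), z0 = D/30, and the Rouse profile
  normalised to 1 at the bedload top; adaptive quadrature at relative
  tolerance 1e-8 with breakpoint hints inside the concentration boundary
  layer when the Rouse number exceeds 5 (the profile then collapses within
  ~H_b/P of the bed and untamed quadrature under-resolves it);
* viscous damping: w_i ramps linearly from 0 to w_s between particle
  Stokes numbers 30 and 75, St = (ρ_s/9ρ_w)(w_sD/ν). In water this damps
  all impacts for grains finer than roughly coarse sand — the mechanism
  behind the cementation-favorable fine-grained zone of the regime maps;
* supply at capacity (the default): an Engelund–Hansen-type relation
  q* = (0.05/C_f)τ*^{5/2} with C_f = (u*/U)², i.e. q ∝ u*⁵, which takes the
  flux smoothly to zero at the threshold. A user-fixed q instead leaves a
  step at threshold (documented behaviour).

Defaults: flow depth H = 1 m, grain density ρ_s = 2850 kg m⁻³ (carbonate —
the impacting grains are carbonate), A₁ = 0.3. Fluxes are "while
transporting" rates; storm intermittency is not modelled, though a
duty-cycle multiplier (default 1) is exposed. Exact regime-map contour
positions depend on these closures and are not a validation surface; the
structural geometry (zero-flux threshold edge, damped fine-grained zone,
monotone response to bioturbation) is.

## Bioturbation flux

Both endmembers are linear in the population-level volumetric reworking
rate R [m³ m⁻² yr⁻¹]:

* **Excavation** (lower bound): lifting the buoyant mass of a cylindrical
  burrow of depth d to the interface costs ½(1−φ)(ρ_s−ρ_w)πb²gd² per
  burrow; converting burrow creation rate to R gives
  dE_gr/dt = ½(1−φ)(ρ_s−ρ_w)Rgd. The package also ships the discrete
  lift-n-slabs sum, whose left-endpoint version converges to the closed
  form at first order (error exactly 1/n) — an internal oracle for the
  integral.
* **Crack propagation** (upper bound): burrowers in cohesive muds extend a
  fracture, dE_cr/dt = 2G_cR/(πb). b is the burrow *radius* (half-width):
  the derivation that converts linear burrowing speed to R through the
  circular cross-section πb² fixes that convention, even though "width" is
  sometimes used loosely for the same symbol. Default G_c = 1 J m⁻² — the
  order of magnitude measured for cohesive marine muds — configurable per
  record.

## Synthetic reworking table

The generator stands in for population-level reworking compilations
(Thayer-style): six functional groups, each with a log₁₀ range of R, a
burrow-radius range, a depth range, and a mechanical mode. Overall R spans
[1e-6, 1e3] m³ m⁻² yr⁻¹ — from whale/ray feeding pits (high individual
impact, very low population rates) to dense deposit-feeding crustaceans
and molluscs — and the pooled median burrow depth is ≈ 0.05 m, matching
the vertical window L of the chemical flux. Crack propagation is evaluated
only for groups whose members actually burrow through cohesive sediment
(meiofauna, polychaetes, molluscs); pit-digging epifauna and bulldozing
echinoderms/crustaceans are excavation-only.

Each group's first two taxa are pinned at the corners of its ranges — an
empirical compilation contains its observed extremes by construction — and
the remaining taxa are log-uniform draws. The pinning makes the *envelope*
of the flux comparison deterministic for every seed while the interior
stays stochastic: bioturbation fluxes span 9.52 decades, and together with
the chemical bands (mud→coarse sand at Ω = 3 and 10) the whole comparison
spans 9.97 decades. What passing span tests show is therefore that the
model reproduces the observed *spread* of benthic energy fluxes under the
configured group structure; they do not validate any individual taxon's
rate, and real compilations have heavier within-group clustering than
log-uniform draws.

## Balance, maps and scenarios

Ratio maps evaluate (E_sed + E_bio)/E_chem over log-spaced grain-size ×
shear-velocity grids. Grain size enters both sides: the numerator through
threshold, damping and capacity, the denominator as D⁻² through A_sp².
Constant bioturbation is added uniformly, so even a small flux puts a
floor under the ratio — the mechanism by which animals shrink, and at high
levels eliminate, the cementation-favorable (ratio < 1) region. The
favorable threshold is the 1:1 line; contour levels {0.01, 1, 100} mark
the two-decade shading convention of regime-map figures. The bioturbation
scenario levels (q25/median/q75) are quartiles, by linear interpolation,
of the pooled *excavation* distribution — the lower endmember, so maps
understate rather than overstate animal influence; the model choice is
configurable.

Quiet-water scenarios use F = E_bio/E_chem and ΔF = F_t2/F_t1 with three
perturbation channels: Ω (scales E_chem by ((Ω₂−1)/(Ω₁−1))ⁿ), biomass
(scales R linearly), and body size (scales b; optionally coupled to R
and/or to burrow depth). Fluxes are recomputed through the formulas at
both times, so channels compose multiplicatively — tested exhaustively on
a perturbation lattice. Scenario magnitudes depend on which channel
multipliers a user supplies (e.g. an alkalinity overshoot Ω 3→10 gives
ΔF ≈ 0.033; a 90 % biomass loss gives ΔF = 0.1 exactly); the package
supplies the algebra, not the historical parameter estimates.

## Numerical choices and problem sizes

* Quadrature: adaptive (QUADPACK) with rel. tol. 1e-8; convergence is
  accepted when the reported absolute error is below max(1e-6·|I|,
  1e-12·UH); failure raises with the offending parameters.
* Quantiles: linear interpolation throughout, so thresholds are bit-for-bit
  reproducible from the same table.
* Grids: the acceptance script uses 100×100 regime maps (seconds of
  runtime); the test suite uses 24×24, which already resolves every
  structural property asserted.
* Degenerate inputs: Ω = 1 yields exactly zero chemical flux (and is
  rejected where a ratio would divide by it); zero supply, sub-threshold
  shear, or fully damped impacts yield exactly zero transport flux rather
  than small numbers; dissolution and buoyant sediment are domain errors.
* Determinism: all stochastic paths flow through one integer seed; the
  transport and cementation paths are pure functions (repeated calls are
  bitwise identical).

## Known limitations

Fluxes are order-of-magnitude comparators, not process-resolved
predictions: the transport closures are interchangeable with other
literature choices and shift contour positions by factors of a few; G_c
for real substrates varies over an order of magnitude; the excavation
model ignores particle diffusion and rotation (hence "lower bound"); and
the chemistry side has no carbonate-system speciation — Ω is an input, not
a computed quantity.
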