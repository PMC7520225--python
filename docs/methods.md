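# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical machinery, and what the synthetic
data generator does and does not emulate.

## Tracer standardization (isotope)

Water-channel signals are converted to deuterium excess,
`δe = δ²H − (8 δ¹⁸O + 10)` (‰), before any other processing. Evaporative
enrichment moves δ²H and δ¹⁸O together along a slope-8 line, so δe is
insensitive to it while responding fully to the injected ²H label. Raw δ²H
is kept only for quality control: the fraction of treated samples
exceeding the control mean + 2 SD per depth is the standard field check
that the label, not contamination, drives the signal.

For a species in one replicate plot labelled at depth *n*, the replicate
uptake proportion is `(S_n − C) / Σ_n (S̄_n − C)`, with `S_n` the
within-plot mean of the 2–4 tissue subreplicates, `S̄_n` the cross-plot
mean at that depth, and `C` the control mean (pooled per campaign by
default; per-season or global pooling is configurable). Negative
numerators are noise and are clamped to zero (and replicates capped at 1)
so every replicate is a valid beta-likelihood response in [0, 1]; the
clamped mass is recorded on the profile.

Two growth-form aggregates are produced, for different consumers:

* **replicate-mean profile** — the mean of the clamped species-plot
  replicate proportions per depth, renormalized. This is what the beta
  regressions fit (they need the replicate-level spread).
* **pooled profile** — growth-form depth means of the *unclamped*
  `S − C` differences, clamped only after averaging, then normalized.
  Averaging before clamping is unbiased where the true signal is near
  zero, whereas a mean of clamped replicates inflates the deep tail by
  `E[max(noise, 0)] > 0`; since D50 and the soil-model root input are
  sensitive to exactly that tail, the pooled profile feeds the
  rooting-distribution assembly.

The nitrogen channel is identical with δ¹⁵N as the signal and no
deuterium-excess transform.

## Continuous profiles and model selection (profiles)

Replicate proportions are fitted against depth by maximum likelihood under
a beta distribution with a logit mean link, the mean being a cubic
B-spline. The knot count is the basis dimension (4 by default, 5 for the
six-depth campaign); interior knots sit at quantiles of the observed
injection depths, and the basis spans the observed depth range — outside
it the curve is continued at a constant value on the logit scale, because
the tracer carries no shape information there. Exact 0/1 responses are
pulled off the boundary with the standard compression
`y' = (y (N − 1) + 0.5) / N`. Optimization is BFGS with a logit-scale
least-squares start and a Nelder–Mead fallback; `df` is the coefficient
count plus one precision parameter and `AIC = 2 df − 2 logLik`
(unpenalized ML — reproducible df accounting rather than an
effective-degrees-of-freedom approximation).

`compare_pooling` fits one shared curve ("all together", df = k + 1) and a
single joint likelihood with an independent curve per growth form and one
shared precision ("all separate", df = 2k + 1). Responses are compressed
once on the combined data so the two log-likelihoods are comparable.
Every candidate within 2 AIC of the best is reported as supported.

Grids are cell-based: a length-125 density covers 1-cm cells over
0–125 cm. `per_cm` divides stratum totals by stratum thickness; the
15-cm running mean truncates and renormalizes its window at the domain
edges; D50 interpolates linearly inside the crossing centimeter and
reports the shallowest crossing on a flat stretch.

## Rooting distributions from tracer profiles (soilwater)

Campaign proportions are treated as point samples of relative per-cm root
activity at the injection depths: linear interpolation between depths,
constant continuation above the shallowest depth, linear decay to zero at
the column bottom below the deepest, then normalization. (Dividing point
proportions by surrounding stratum thicknesses was rejected: it is the
right transform for stratum *totals* but systematically distorts D50 for
point samples.) A season-long, piecewise-constant-in-time distribution
applies each campaign's profile from the midpoint to the previous campaign
through the midpoint to the next; every time slice is normalized.

## Soil water flow and uptake (soilwater)

The column model solves the mixed-form Richards equation on cell-centered
finite volumes (1-cm cells over 0–125 cm by default) with:

* **hydraulics** — van Genuchten retention
  `θ(h) = θr + (θs − θr)(1 + |αh|ⁿ)^(−m)`, Mualem conductivity
  `K = Ks Se^l (1 − (1 − Se^{1/m})^m)²`. Defaults are Rosetta-class
  values for a fine-textured clay profile (θr 0.089, θs 0.43,
  α 0.01 cm⁻¹, n 1.23, Ks 6.2 cm/d, l 0.5); site-specific parameters are
  configuration inputs (no pedotransfer model is bundled).
* **root uptake** — uncompensated Feddes sink
  `S(z,t) = α(h) b(z) Tp` with the alfalfa thresholds
  (−10, −25, −200, −8000 cm) from the standard crop database; no
  redistribution of unmet demand.
* **forcing** — FAO-56 daily Penman–Monteith reference ET from the daily
  weather table, split into potential transpiration
  `Tp = ET₀ (1 − e^{−k·LAI})` (k = 0.463) and potential soil evaporation.
  LAI defaults to 0.024 per cm of a 60-cm canopy (1.44). Interception is
  a simple canopy store of 0.025 cm per unit LAI per rain day. Daily
  forcing is applied as constant rates.
* **boundaries** — rain enters through the surface, limited smoothly
  (soft-min with width 10⁻³ of the surface conductivity) by the Darcy
  flux a ponded surface could accept; the excess is runoff. Soil
  evaporation is a supply-limited *sink* over the top 15 cm (exponential
  extraction profile, e-folding 3 cm) scaled by a log-linear
  pressure-head ramp from full supply at −10³ cm to zero at the air-dry
  head −10⁵ cm; treating evaporation as a sink rather than an upward
  boundary flux removes the stiffest nonlinearity of dry-surface
  simulation. The bottom is free drainage (unit gradient) or optionally
  no-flow.

**Numerics.** Each substep is a damped Newton iteration on the cell mass
residual: geometric-mean internodal conductivities (arithmetic means let
the wet cell dominate sharp clay wetting fronts), analytic dK/dh terms in
the tridiagonal Jacobian, chord-slope storage linearization, Thomas
solves, and a backtracking line search on the residual norm. Near
saturation the retention curve is regularized in the standard two ways —
a −2 cm air-entry head (Vogel–Císlerová form, keeping the moisture
capacity nondegenerate for n < 2 soils) and an elastic specific storage of
10⁻⁴ cm⁻¹ above it — both confined to within ~5·10⁻⁴ of the closed form
and to heads in (−2, 0] cm and ponded states; the public closed-form
functions are exact. The inner kernels are numba-compiled.

The water content carried between substeps is the *flux-consistent* one
(`θ ← θ + (fluxes − sinks) Δt/Δz`), so the season water balance closes to
machine precision by construction; the per-cell residual tolerance
(10⁻⁴ cm per substep) bounds the non-accumulating gap between that state
and θ(h), which is reported as `theta_drift`. The tolerance was fixed
after checking that tightening it 10× changes season totals by < 0.01%.
Time steps adapt between 10⁻⁶ and 0.2 d on iteration count. Pulse
infiltration at this resolution agrees with a 0.1-cm fine-grid run of the
same equations within 3% on season-total uptake, and halving Δz and Δt
changes it by < 1% (both are acceptance tests).

Matric-potential sensors convert through 1 MPa = 10197.16 cm and the
retention curve; `compare_vwc` regresses observed on predicted water
content (OLS) and reports RMSE about the 1:1 line.

## Niche statistics (niche)

Total uptake sums the field over depths and days. The unique niche sums
the positive part of `U_i − max_{j≠i} U_j` over the index set — by
default per depth on season-summed uptake (mirroring a depth-only
definition); the per-(depth, day) mode can only be larger, since a max of
sums never exceeds a sum of maxes. For two distributions,
`unique_i − unique_j = total_i − total_j` holds exactly in either mode.
Percent differences are reported signed, with nearest-percent rounding
for prose. Mean depth of uptake is the D50 of season-summed per-cm
uptake.

## Synthetic campaign (synthetic)

The generator reproduces the study layout: two 243-day growing seasons
(October–May) with rain targets 587 and 866 mm; three campaigns per
season; depth sets {5, 10, 20, 30, 50, 100} cm in season one (30 cm in
the first campaign only) and {10, 20, 30, 50, 70} cm in season two; three
replicate plots per depth plus pooled control plots; ten common species
(five per growth form) with 2–4 tissue subreplicates per species-plot,
which reproduces the field campaign's sample volume (~575 plant samples
in a six-depth campaign).

Ground-truth rooting densities are Weibull-shaped per-cm profiles whose
scale is solved so the discrete D50 hits the target (tree 22 cm, grass
17 cm by default; the ¹⁵N channel has its own, tree 15 / grass 18 cm).
The tracer signal model is deliberately minimal, consistent with one-day
uptake after injection: the expected uptake fraction from labelled depth
*d* is `f_d ∝ b(d)·α(h_d)` normalized over the campaign's depth set
(α ≡ 1 without a soil-state input — sampling dates are chosen for moist,
plant-available conditions), and
`δe = control_mean + 200‰ · f_d + N(0, 30‰)`. The 200 ‰ label strength
was set so per-depth exceedance of the control mean + 2 SD spans roughly
the 16–51% range reported for such campaigns; the 30 ‰ noise mirrors the
control SD (−65 ± 30 ‰ generating values; δ²H/δ¹⁸O are back-computed
consistently with the δe definition around a −6 ‰ δ¹⁸O baseline).
Weather is a marked Bernoulli–Gamma rain process scaled to the season
target, with seasonal sinusoids plus bounded noise for temperature,
humidity, radiation, and wind. Everything derives from one master seed
through spawned substreams, so outputs are bitwise reproducible.

Not emulated: tracer plume movement between depths, isotopic
fractionation during uptake, species-level rooting differences within a
growth form, spatial autocorrelation among plots, and weather
persistence beyond independent wet days. Passing recovery tests
therefore show the *pipeline* is unbiased under its own signal model at
field-scale noise, not that field data meet these assumptions.

## Known limitations

* The uptake simulation inherits all 1D Richards assumptions: no
  hydraulic redistribution, vapor flow, hysteresis, or compensated
  uptake, and a single stereotyped canopy per run.
* Spline df accounting is exact-parameter-count ML, not penalized-edf;
  AIC values are therefore not comparable to mixed-model effective df.
* A 10-cm D50 separation at field replication sits near the detection
  threshold of the AIC comparison when profiles are deep; detection is
  reliable when at least one profile is shallow (stronger per-depth
  signal contrast).
* The evaporation-as-sink formulation slightly reallocates near-surface
  water between evaporation and shallow uptake relative to a
  boundary-flux formulation; season totals are insensitive, but
  cm-scale surface detail should not be over-interpreted.
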