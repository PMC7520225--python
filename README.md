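# hydroniche

Quantifying vertical water-resource partitioning between plant growth
forms — typically savanna trees versus grasses — from depth-specific
isotope tracer experiments.

Root *biomass* says little about where plants actually take up water. A
pulse-chase experiment does: labelled water (²H₂O) is injected at a known
soil depth, plant tissue is sampled days later, and enrichment above
control plants reveals active roots at that depth. `hydroniche` turns such
point-in-time measurements into continuous, season-long estimates of water
uptake by depth, and from those computes two niche statistics:

* **total water uptake index** — the sum of simulated uptake over all
  depths and days of a growing season for one rooting distribution,
  `T_i = Σ_d Σ_t U_{i,d,t}`;
* **unique hydrological niche index** — the water one distribution
  extracts in excess of its best competitor at each depth,
  `N_i = Σ_d max(U_{i,d} − max_{j≠i} U_{j,d}, 0)` (uptake season-summed
  per depth by default; a per-(depth, day) mode is available).

The pipeline has four stages, each usable on its own:

1. **isotope** — deuterium excess `δe = δ²H − (8 δ¹⁸O + 10)` (removes
   evaporative enrichment), control summaries (mean ± SD, mean + 2 SD
   exceedance QC), and control-corrected proportional uptake by depth
   `(S_n − C) / Σ_n (S̄_n − C)`; a δ¹⁵N channel handles nitrogen tracers.
2. **profiles** — beta-likelihood B-spline fits of proportion against
   depth (logit link), AIC comparison of pooled versus growth-form-specific
   curves, per-cm conversion, 15-cm running averages, and D50 (the depth
   above which half the mass lies).
3. **soilwater** — a mass-conservative 1D Richards-equation column
   (van Genuchten–Mualem hydraulics, Feddes root-water-uptake stress,
   FAO-56 Penman–Monteith forcing) that converts a rooting distribution
   plus daily weather into per-cm daily water uptake.
4. **niche** — the two indices above, mean depth of uptake, and percent
   differences between distributions.

A `synthetic` module generates every input the pipeline needs — weather,
soils, "true" rooting profiles, and noisy tracer sample tables laid out
like a real two-season field campaign — with known ground truth, so the
whole chain is testable without field data.

## Worked example

`examples/03_niche_indices.py` runs the same drier season (587 mm target)
twice, once per rooting distribution, everything else identical:

```
 tree: total uptake  25.85 cm, unique niche  2.20 cm
grass: total uptake  25.21 cm, unique niche  1.56 cm
tree vs grass: +2.53% (reported as +3%)
identity check: unique_t - unique_g = 0.638339 = total_t - total_g = 0.638339
```

The tree-like distribution (D50 = 22 cm, half its uptake above 22 cm)
extracts ~3% more water this season than the grass-like one (D50 = 17 cm),
and each still has ≥ 1.5 cm of water only it can reach — a resource
pool that supports coexistence even under near-total root overlap. The
final line verifies the exact algebraic identity linking the two indices
for a pair of distributions. The other examples cover tracer
standardization, a single season's water balance, AIC model selection, and
the nitrogen channel.

There is also a thin CLI:

```sh
hydroniche synth --seed 1 --outdir data/        # write scenario inputs
hydroniche uptake --samples data/samples_2010-11-15.csv --out profiles.csv
hydroniche simulate --weather data/weather_2010-11.csv --roots profiles.csv \
    --group tree --out tree_uptake.csv
hydroniche niche --uptake-a tree_uptake.csv --uptake-b grass_uptake.csv
hydroniche pipeline --seed 1 --outdir run/      # all stages at once
```

## Layout

```
src/hydroniche/      isotope, profiles, soilwater (+ _richards kernels),
                     niche, synthetic, pipeline, io, cli
examples/            one short narrative script per capability
tests/               unit, property, and end-to-end acceptance tests
docs/methods.md      model descriptions, defaults, numerical choices
```
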