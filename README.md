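# springtail-metrics

Trait-based analysis of soil springtail (Collembola) community samples:
from raw site × sample × taxon abundance tables to site-level density,
biomass, community metabolism and species richness, latitudinal and
ecosystem summaries, and grid-based global extrapolation with uncertainty.

Springtails are among the most abundant soil arthropods on Earth; their
density, biomass and energy use are key metrics of belowground food webs.
Compilations of heterogeneous soil-core surveys require a reproducible
chain of conversions and corrections before such metrics can be compared
across sites — that chain is what this package implements, for ecologists
working with soil mesofauna community data.

## What it computes

**Individual masses and metabolism.** Genus-level body lengths *L* (mm)
are converted to dry mass with group-specific log–log allometric
regressions, log₁₀ *m* = *a* + *b* log₁₀ *L* (several regressions per
morphogroup are averaged), then to fresh mass with group conversion
factors. Individual metabolic rate follows the metabolic theory of
ecology with insect coefficients:

    ln I = ln(i0) + a ln M − E / (k T)

with *I* in J h⁻¹, *M* fresh mass in mg, ln(*i0*) = 21.972, *a* = 0.759,
*E* = 0.657 eV, *k* = 8.617 × 10⁻⁵ eV K⁻¹ and *T* the mean annual topsoil
temperature in kelvin. Coefficient uncertainty propagates through
min / mean / max variants (coefficients shifted by ± 1 SE).

**Site metrics.** Density = mean over samples of individuals per m²;
biomass and community metabolism = per-sample totals per m², averaged
across samples; community-weighted mean body mass and metabolic rate are
computed per sample and 10 %-trimmed-averaged across samples.

**Richness.** Sample-based analytic rarefaction, the incidence-based Chao
estimator *S*̂ = *S*obs + ((m−1)/m) · Q₁(Q₁−1) / (2(Q₂+1)), sampling
completeness *S*obs/*S*̂, and a binomial GLM
(`completeness ~ n_samples * latitude`) that back-corrects observed
richness at sites with only pooled species lists.

**Quality filters, gradients, maps.** Documented technical selection
rules (sampled-layer rules, low-density outlier flags, minimum sampling
effort for richness); 5-degree latitudinal-belt and ecosystem-type
summaries; and a mapping pipeline: an ensemble of the 10 best of 18
random-forest configurations ranked by 10-fold CV R², a PCA convex-hull
interpolation mask, spatially stratified bootstrap uncertainty layers,
area-weighted global totals and energy → carbon conversion
(1 kg fresh mass = 7 × 10⁶ J, 70 % water, 45 % C of dry mass).

A seed-driven synthetic-data generator (`springtail_metrics.simulate`)
emulates the structure of global compilation data with known ground
truth, so the whole pipeline is testable offline.

## Worked example

```python
import springtail_metrics as sm

# the metabolic equation: a 0.01 mg springtail at 10 °C
sm.individual_metabolic_rate(0.01, 283.15) * 1e3   # -> 0.2138 mJ per hour

ds = sm.generate_dataset(sm.GeneratorConfig(n_sites=12, seed=4))
m = sm.compute_site_metrics(ds.samples, ds.sites, ds.traits)
print(m[["site_id", "n_samples", "density", "dry_biomass",
         "community_metabolism"]].head(3).round(2).to_string(index=False))
```

```
  site_id  n_samples  density  dry_biomass  community_metabolism
site_0000          6 20416.67        50.32                  1.96
site_0001          8  6375.00        51.15                 10.34
site_0002          8  2375.00         4.01                  0.55
```

Density is individuals m⁻², dry biomass mg m⁻², community metabolism
J h⁻¹ m⁻² — site 0 hosts ~20 000 springtails per m² whose summed
respiration runs at ~2 J per hour per m². Richness extrapolation:

```python
print(sm.site_richness_table(ds.samples).head(3).round(3).to_string(index=False))
```

```
  site_id  n_samples  s_obs  s_chao  completeness
site_0000          6     22  22.000         1.000
site_0001          8     20  20.525         0.974
site_0002          8     13  19.562         0.665
```

Site 2's 13 observed species extrapolate to ~19.6 (many species seen in a
single sample), i.e. the inventory is ~67 % complete.

The same stages are exposed as a CLI
(`springtail-metrics simulate | ingest | compute-metrics | qc |
extrapolate-richness | summarize | map-ensemble`).

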