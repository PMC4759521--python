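# elevdiv

Spatial analysis of species diversity along elevational gradients, built for
macroecological studies of montane clades (the motivating system is the
Andean rain frogs, genus *Pristimantis*, on the 500–5000 m gradient of the
tropical Andes).

Given (1) a table of species elevational ranges (minimum and maximum record
per species) and (2) a digital elevation model per region, the package
computes, per 500-m elevational band:

* **gamma richness** by range interpolation — a species is assumed present at
  every elevation between its recorded minimum and maximum;
* **band area** (km², cosine-weighted geographic cells) and **topographic
  ruggedness** (TRI: per cell, `sqrt(Σ (e_c − e_n)²)` over the 8 neighbours);

and then tests the classical spatial hypotheses for the shape of the
richness curve:

* **Species–area relationship (SAR)** — OLS in three forms: linear
  (`S ~ A`), semilog (`S ~ log A`) and curvilinear (`log S ~ log A`, the
  power law `S = cA^z`), compared by small-sample AICc with Akaike weights;
  a **global z** pooled over gradients with significant power-law SARs
  (mean log–log slope with a t-based 95 % CI) feeds a shape-preserving
  area correction `S_corr = S / A^z`.
* **Mid-domain effect (MDE)** — a Monte-Carlo null model: each simulation
  places the full empirical multiset of range sizes at uniform random
  feasible midpoints within the domain `[floor, mountain top]`, yielding a
  per-band mean null richness and 95 % percentile envelope; the empirical
  (and area-corrected) curve is regressed on the null mean with linear and
  quadratic fits.
* **Topographic heterogeneity** — the same three regression forms with band
  mean TRI (optionally TRI/√area) as the predictor.
* **Latitudinal effect** — across mountain ranges, four models (richness ~
  |latitude|; + mid-elevation; + TRI; intercept-only) with AICc-weighted
  natural model averaging of the coefficients.

A seeded synthetic-data module generates range tables and ridge-shaped DEMs
with known structure (midpoint-uniform "MDE-true" sets, niche-clustered
humps, plateau hypsometries), so the entire pipeline runs and is tested
without any downloads.

## Worked example

A synthetic stand-in database at the scale of the Andean *Pristimantis*
compilation (378 species, records from 500 up to 4538 m), interpolated into
nine 500-m bands and compared with its mid-domain null model:

```python
from elevdiv import (BandScheme, Domain, inflate_point_ranges, make_study_standin,
                     richness_per_band, simulate_mde, fit_empirical_to_mde)

scheme = BandScheme(base=500, width=500, n_bands=9)
species = inflate_point_ranges(make_study_standin(seed=0), delta=5.0)
profile = richness_per_band(species, scheme)
print(profile.to_frame().to_string(index=False))

domain = Domain(500, max(r.elev_max for r in species))   # observed limits
null = simulate_mde(species, domain, scheme, n_sims=5000, seed=0)
fits = fit_empirical_to_mde(profile, null)
print(fits.to_frame()[["form", "F", "df1", "df2", "p", "adj_r2", "AICc", "weight"]]
      .round(4).to_string(index=False))
```

```
 band_low  band_high  band_mid  richness
      500       1000     750.0        62
     1000       1500    1250.0       101
     1500       2000    1750.0       174
     2000       2500    2250.0       199
     2500       3000    2750.0       192
     3000       3500    3250.0       154
     3500       4000    3750.0       101
     4000       4500    4250.0        47
     4500       5000    4750.0        23
     form        F  df1  df2      p  adj_r2    AICc  weight
   linear  58.5198    1    7 0.0001  0.8779 90.4082  0.0451
quadratic 120.1606    2    6 0.0000  0.9675 84.3023  0.9549
```

The richness curve is hump-shaped, peaking at 2000–2500 m. The null model —
pure geometry, empirical range sizes shuffled within the domain — explains
most of its variance (linear adjusted r² 0.88; the quadratic fit, adjusted
r² 0.97, carries almost all the Akaike weight), which is the signature of a
strong mid-domain component in a niche-clustered gradient.

## Command line

```sh
elevdiv fixtures --out toy --seed 1          # synthetic mountain system
elevdiv all --config toy/config.yaml --out toy/report
elevdiv richness --ranges toy/ranges.csv --out profile.csv
elevdiv mde --ranges toy/ranges.csv --out mde.csv --n-sims 50000 --seed 1
```

`elevdiv all` writes per-gradient richness/area/TRI tables, the MDE envelope
(`mde_<region>.csv`), a tidy table of every fitted model (`fits.csv`), and
`run_log.json` with the seed, the chosen domain limits and any per-stage
failures.

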