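# colonyforage

Tools for asking whether the *patchiness* of the marine environment around a
seabird breeding colony — not its average state — shapes how the birds forage
and how many chicks they raise. The package implements the full analysis chain
for colonial central-place foragers such as black-legged kittiwakes
(*Rissa tridactyla*), plus a synthetic-world generator with known ground truth
so every stage can be verified end to end.

## What it computes

1. **Environmental heterogeneity (H).** Six gridded variables (bathymetry,
   potential tidal stratification, SST, ocean-front strength / distance /
   persistence) are sampled within each colony's foraging radius and
   standardized jointly. H for a colony-year is the mean distance of its grid
   cells from their group centre (spatial median or centroid) in that
   six-dimensional space — the multivariate-dispersion statistic, identical in
   the full PCoA ordination because Euclidean PCoA is an isometry. Group
   differences are tested with the PERMDISP permutation F test; colony and
   year effects with a two-way ANOVA + Tukey HSD.
2. **Foraging trips.** GPS fixes are filtered (23:00–03:00 local masked,
   fixes within 500 m of the colony excluded) and segmented into trips longer
   than 14 min; per-trip duration, total path length and maximum range feed
   colony-year means.
3. **Behaviour.** Trips are regularized to a fixed time step and classified
   into rest / forage / transit with a 3-state hidden Markov model (gamma step
   lengths, von Mises turning angles), fitted by direct numerical maximum
   likelihood and decoded with the Viterbi algorithm; per-bird time budgets
   are the proportions of decoded positions per state.
4. **Space use.** Fixed-kernel utilization distributions on a 1 km
   colony-anchored grid (reference bandwidth h = σ·n^(−1/6)), 50% core
   foraging areas, and Bhattacharyya affinity BA = Σ√(p·q) between all pairs
   of birds in a colony-year as a proxy for competition.
5. **Inference.** A regression suite on standardized colony-mean H: log trip
   metrics (OLS, F), time budgets (quasi-binomial logit, F), core-area size
   (OLS, F), pairwise overlap (Gaussian mixed model, focal-bird random
   intercept, χ² likelihood-ratio test), breeding success in fledglings per
   nest (OLS, F, R², percent decline across the observed H range), and
   confound screens.

The synthetic generator builds worlds in which heterogeneous colonies have
more forage-heavy time budgets, longer trips, fewer shared foraging hotspots
(hence more overlap) and lower breeding success, while total and maximum trip
distance, rest time and core-area size carry no effect — so the expected
qualitative outcome of the whole chain is known in advance and tested.

## Worked example

```python
import colonyforage as cf
from colonyforage.pipeline import table2_pattern

config = cf.endtoend_world(n_colonies=6, n_years=2, n_birds=4, n_fixes=300, seed=7)
results = cf.run_pipeline(config, seed=7, n_perm=199)

print(results["colony_mean_H"].round(2).to_string())
print("PERMDISP: F = %.1f, p = %.3f" % (results["permdisp"].F, results["permdisp"].p))
for name, r in results["table2"].items():
    print(f"{name:18s} estimate {r.estimate:+.3f}  {r.stat_name} = {r.statistic:7.2f}  p = {r.p:.4f}")
print("percent decline in breeding success: %.1f%%" % results["percent_decline"])
```

prints (about a minute on one CPU):

```
colony_id
colony00    1.52
colony01    1.84
colony02    2.19
colony03    2.16
colony04    2.72
colony05    2.93
PERMDISP: F = 104.5, p = 0.005
p_forage           estimate +0.240  F =    8.64  p = 0.0051
p_transit          estimate -0.221  F =   10.24  p = 0.0025
p_rest             estimate -0.033  F =    0.16  p = 0.6936
mean_duration_hr   estimate +0.102  F =    4.47  p = 0.0605
mean_total_km      estimate -0.026  F =    0.26  p = 0.6237
mean_max_km        estimate -0.034  F =    0.87  p = 0.3716
ba_overlap         estimate +0.046  chi2 =    3.91  p = 0.0480
core_area_km2      estimate -7.041  F =    4.04  p = 0.0505
breeding_success   estimate -0.228  F =   46.32  p = 0.0000
percent decline in breeding success: 55.8%
```

Colony-mean heterogeneity rises from colony00 to colony05, and with it the
proportion of time spent foraging (+0.24 per SD of H on the logit scale),
overlap between individuals (+0.046 BA per SD) and the decline in breeding
success (−0.23 fledglings·nest⁻¹ per SD, a 55.8% drop across the observed
range), while time spent transiting falls and total distance, maximum range,
rest time and core-area size show no effect. At this miniature scale (12
colony-years, 48 birds) the trip-duration trend is positive but just misses
α = 0.05; the acceptance suite runs 20 larger worlds where it resolves
clearly.

Ground truth for any world is available from `config` and
`cf.synth.save_truth(config, "truth.yaml")`; raw inputs (fix tables, rasters,
success tables) come from `cf.generate_world(config)`.

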