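# coreniche

Tools for analysing spatiotemporal marker-gene (ASV) surveys of coastal
plankton: prioritising the **core** community by abundance–occupancy,
assigning **trophic modes** (autotroph / heterotroph / mixotroph), screening
**environmental drivers**, and locating the **multi-stressor niche optimum**
of core mixoplankton with a hierarchical GAMM ladder.  A synthetic-survey
generator with planted, recorded ground truth makes every stage verifiable by
parameter recovery at desk scale.

## Who it is for

Microbial ecologists with a samples × ASV count table from a station × month
survey, a PR2-style taxonomy with a trophic-mode column, and a per-sample
table of environmental variables, who want a reproducible route from raw
counts to "which taxa are core, which stressors matter, and where is the
mixoplankton optimum".

## The methods at the core

* **Core selection.** Taxa are ranked by a blend of overall occupancy and
  temporal occupancy (mean over months of the within-month station
  occupancy).  The contribution curve C(k) is the fraction of total pairwise
  Bray–Curtis similarity, `BC(i,j) = 2·Σ_t min(x_it, x_jt) / (N_i + N_j)`,
  explained by the top-k ranked taxa; the core is cut at the last rank whose
  relative gain `(C(k) − C(k−1))/C(k−1)` exceeds 1%.
* **Neutral model.** Sloan's neutral expectation
  `occ(p) = 1 − I_{d/Nt}(Nt·m·p, Nt·m·(1−p))` is fitted to the
  abundance–occupancy cloud by least squares over the migration rate *m*,
  with a 95% Wilson band classifying taxa as above/within/below neutral.
* **Diversity.** Shannon/richness with Kruskal–Wallis + pairwise rank-sum
  (BH-adjusted) seasonal tests; Bray–Curtis PCoA with the Lingoes correction
  and PERMANOVA (999 permutations); ordinary kriging of station-level Shannon
  fields from a WLS-fitted semivariogram with leave-one-out validation.
* **Driver screening.** Variance partitioning (partial RDA on
  Hellinger-transformed counts, Ezekiel-adjusted R²) across Nutrient /
  Physicochemistry / Geography; partial Mantel tests controlling for
  geographic distance; random-forest permutation importance (%IncMSE over
  1000 trees) with a response-permutation significance test.
* **Niche model.** The mixoplankton relative proportion is
  log10-transformed (ε = 1e-4), outliers with |z| > 3 removed, predictors
  VIF-screened, and four nested penalized-spline GAMMs fitted:
  M1 = s(T) + s(DO) + s(NO₃-N) + station random intercept; M2–M4 add the
  pairwise tensor interactions ti(T,DO), ti(T,NO₃-N), ti(DO,NO₃-N).  The
  lowest-AIC model predicts on a 50³ grid over the central (2nd–98th
  percentile) stressor box; the optimum (T\*, DO\*, N\*) is the grid argmax.

## Worked example

```python
from coreniche import SimConfig, simulate_survey, CommunityMatrix
from coreniche.core import compute_occupancy, contribution_curve, select_core, core_fraction
from coreniche.niche import NicheLadder, clean_response
from coreniche.trophic import annotate_trophic, trophic_profile
import pandas as pd

counts, taxonomy, env, truth = simulate_survey(SimConfig(seed=1))
m = CommunityMatrix(counts, env[["station", "month", "season", "latitude", "longitude"]])

occ = compute_occupancy(m)
curve = contribution_curve(m, occ.index.tolist())
core = select_core(curve, gain=0.01)
print(len(core), core_fraction(len(core), m.n_taxa))

profile = trophic_profile(m, annotate_trophic(taxonomy), core)
data = pd.DataFrame({
    "response": profile.per_sample["prop_mixotroph"],
    "temperature": env["temperature"], "DO": env["DO"], "NO3-N": env["NO3-N"],
    "station": m.metadata["station"],
})
fit = NicheLadder(data=clean_response(data, "response")).fit()
optimum, value, boundary = fit.locate_optimum()
print(fit.selected, optimum)
```

prints

```
823 16.5
M1 {'temperature': 18.66352259390436, 'DO': 3.1187306444904173, 'NO3-N': 0.524401904338311}
```

i.e. the last-1%-gain rule selects 823 of 5000 ASVs (16.5% of the community)
as core — the generator planted 900, all 823 selected are planted core — and
the selected GAMM locates the mixoplankton optimum near the planted
(18.0 °C, 3.5 mg/L DO, 0.64 mg/L NO₃-N) bowl centre (off by about 0.7 °C,
0.4 mg/L and 0.12 mg/L on this seed).

The same chain runs from the shell:

```bash
coreniche simulate --seed 1 --outdir survey/
coreniche run --config cfg.yaml          # full pipeline + run_report.json
```

where `cfg.yaml` names either the four input files (ASV TSV/BIOM, taxonomy
TSV, metadata CSV, environment CSV) or a `simulate:` block.

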