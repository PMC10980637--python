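# wintercjs

Capture–mark–recapture survival analysis for birds whose **wintering
strategy** (migratory flyway × migration distance) may drive their survival
— built around the study design of a colour-ringed Eurasian spoonbill
(*Platalea leucorodia*) population breeding at a single Mediterranean
colony and wintering from the Atlantic coast of Africa to Italy.

## The problem and the model

Chicks are ringed at the colony, but an individual only enters the analysis
at its **first winter sighting**, which also reveals its wintering region
(EAF LD, EAF SD, CEF LD, CEF SD or RES — East Atlantic / Central European
flyway, long-distance / short-distance / resident). All later information
comes from annual breeding-season resightings at the colony. This yields a
Cormack–Jolly–Seber (CJS) model with a bespoke structure:

* **Φ¹** — apparent survival over the *half-year* from winter entry to the
  next breeding season, modelled per age class (immature / adult, with
  adulthood from the fourth calendar year) and wintering region;
* **Φ²⁺** — apparent survival over each subsequent *annual* interval;
* **p** — breeding-season resighting probability by age class (2 cy / 3 cy /
  4+ cy), migration distance, and effort period, with 2008–2013 fixed to
  zero (no colony resightings despite effort) and a camera-trap effort jump
  from 2016.

Model structure is selected by a two-step stepwise sweep ranked by

```
QAICc = deviance/ĉ + 2K + 2K(K+1)/(n − K − 1)
```

where the overdispersion coefficient ĉ = χ²/df comes from U-CARE-style
goodness-of-fit components (TEST2.CT, TEST2.CL, TEST3.SM; TEST3.SR is
absorbed by the Φ¹/Φ²⁺ split). Among models within two QAICc points the one
with fewest parameters wins. Because a single-colony design confounds death
with permanent emigration, spring/summer resightings away from the colony
give a deterministic correction: true survival ≈ Φ / (1 − emigration
fraction).

A seeded synthetic-cohort generator with the same structure (five uneven
groups, delayed maturity, fixed-zero years, optional transients and
permanent emigrants) makes every stage testable without the field data.

## Worked example

```python
import wintercjs as w

cfg = w.default_config(seed=1)          # 484 birds, Table-2-shaped groups
dataset, away, truth = w.simulate(cfg)

marray = w.build_marray(dataset)
print(w.gof_report(marray).to_string(index=False))

spec = w.ParameterSpec.parse("phi1 ~ 2age + dis; phi2 ~ 2age; p ~ ct + 3age + dis")
fm = w.fit(spec, dataset, seed=1)
print(f"K = {fm.K}, deviance = {fm.deviance:.1f}")
```

prints

```
component  statistic  df      p_value
 TEST3.SR  96.115875   8 2.649891e-17
 TEST3.SM   2.191091   4 7.006607e-01
 TEST2.CT   3.190604   7 8.668277e-01
 TEST2.CL   6.257474   8 6.184154e-01
K = 12, deviance = 1731.8
```

TEST3.SR rejects strongly even though the generator contains no transients:
newly marked birds face a half-year interval with lower survival than the
annual intervals of previously seen birds, which is exactly the
time-since-marking signal the Φ¹/Φ²⁺ split absorbs. The other components
are null, so ĉ stays at its floor of 1. The fitted half-year survival with
95% profile-likelihood intervals:

```
phi1 imm  LD: 0.31 [0.25, 0.38]
phi1 imm  SD: 0.74 [0.61, 0.85]
phi1 imm RES: 0.74 [0.57, 0.90]
phi1  ad  LD: 0.62 [0.43, 0.80]
phi1  ad  SD: 0.91 [0.80, 0.97]
phi1  ad RES: 0.91 [0.78, 0.98]
```

Long-distance migrants survive the post-winter half-year markedly worse
than short-distance migrants and residents, in both age classes — the
pattern the generator encodes and the estimator recovers.

The same flow runs end to end from the shell:

```
wintercjs simulate --seed 1 --out cohort.csv
wintercjs gof --data cohort.csv
wintercjs fit --data cohort.csv --model "phi1 ~ 2age + dis; phi2 ~ 2age; p ~ ct + 3age + dis"
wintercjs run --config analysis.yaml --out-dir results/
```

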