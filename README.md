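# postfire-mca

Participatory multi-criteria assessment of burned landscapes: the package
maps **post-fire soil erosion risk (SER)** and **post-fire vegetation
recovery potential (VRP)** from georeferenced criterion layers, with
criterion weights elicited from experts and stakeholders through the
**Analytic Hierarchy Process (AHP)**, robustness checked by Monte-Carlo
weight perturbation, and predictions validated against circular field
plots. It is aimed at fire ecologists and land managers who need a
transparent, re-weightable first assessment of a burn scar shortly after
the fire, and at method developers who want every stage runnable and
testable on synthetic fixtures without any data download.

## The model

Criterion weights come from pairwise comparisons on the Saaty 1–9 scale,
organized in a positive reciprocal matrix *A* (a<sub>ji</sub> = 1/a<sub>ij</sub>).
Weights are the row means of the column-normalized matrix,
*w<sub>i</sub>* = (1/n) Σ<sub>j</sub> a<sub>ij</sub> / Σ<sub>k</sub> a<sub>kj</sub>,
and judgment coherence is screened with the consistency ratio
CR = CI / RI, CI = (λ<sub>max</sub> − n)/(n − 1), accepting CR < 0.1.
Participant weight vectors are averaged for the "democratic" scheme.

Each criterion becomes a raster layer:

| model | criterion | layer | scale |
|---|---|---|---|
| SER | fire severity | dNBR = NBR_pre − NBR_post, NBR = (NIR−SWIR)/(NIR+SWIR) | 0–1 between 0.1 and 0.66 |
| SER | soil erodibility | RUSLE K factor | 0–1 between 0 and 0.55 Mg h ha⁻¹ MJ⁻¹ mm⁻¹ |
| SER | bare soil | BSI = ((SWIR+RED)−(NIR+BLUE))/((SWIR+RED)+(NIR+BLUE)) | 0–1 between −1 and 1 |
| SER | resprouter cover | % of polygon covered by resprouting species | 0–1, saturating at 40 % cover |
| SER | slope | Horn's method on the DEM, in percent | 0–1 between 9 % and 80 % |
| VRP | regeneration capacity | RC = cover-weighted mean strategy rank (resprouter 1, post-fire seeder 2, seeder 3) | 1–3 |
| VRP | fire severity | dNBR classes (<0.27 / 0.27–0.66 / >0.66) | 1–3 |
| VRP | aridity | aridity-index bands (>0.5 / 0.21–0.5 / <0.21) | 1–3 |
| VRP | aspect | N,NE,NW / E,W,SE,SW / S | 1–3 |
| VRP | fire history | max(frequency, immaturity) sub-scores over a 20-year window | 1–3 |

The composites are simple additive weightings inside the burned
perimeter:

```
SER = FSI·w_FSI + K·w_K + BSI·w_BSI − PR·w_PR + Slo·w_Slo        (range [−w_PR, 1−w_PR])
VRP = RC·w_RC + FSI·w_FSI + AI·w_AI + Asp·w_Asp + FH·w_FH        (range [1, 3])
```

Higher values mean greater erosion risk, and greater impediment to
recovery (all VRP inputs score 3 for the least favourable condition).
Sensitivity is assessed by resampling each weight uniformly within ±10,
±20 and ±30 %, renormalizing, and summarizing rank preservation and
pairwise distribution overlap. Validation samples the maps with a 10 m
buffer around each field-plot center and compares them to plot erosion
scores (maximum of the per-type intensity scores) and to height-weighted
shrub/grass cover (1.20 m and 0.10 m stratum heights) via Spearman
correlation, OLS regression and one-way ANOVA.

## Worked example

Deriving weights from one participant's pairwise judgments:

```python
from postfire_mca import build_comparison_matrix, derive_weights, consistency_ratio

m = build_comparison_matrix(
    ["fire_severity", "erodibility", "bare_soil", "resprouters", "slope"],
    {(0, 1): 2, (0, 2): 3, (0, 3): 2, (0, 4): 1,
     (1, 2): 2, (1, 3): 1, (1, 4): 1/2,
     (2, 3): 1/2, (2, 4): 1/3,
     (3, 4): 1/2},
)
w = derive_weights(m)
rep = consistency_ratio(m)
```

prints, per criterion, the normalized weight and the consistency screen:

```
fire_severity  0.298
erodibility    0.158
bare_soil      0.089
resprouters    0.158
slope          0.298
lambda_max=5.0133  CI=0.0033  CR=0.0030  acceptable=True
```

Fire severity and slope carry ~30 % of the weight each; the judgments are
nearly consistent (CR = 0.003 « 0.1), so the weights are usable.

Running the whole pipeline on a generated scenario:

```
postfire-mca synth --seed 1 --out demo/inputs
postfire-mca run --inputs demo/inputs --out demo/results --seed 1
```

`demo/results` then contains the SER/VRP maps and their 3-band versions
(`ser.asc`, `vrp.asc`, `*_bands.asc`), per-participant and averaged
weights, the per-replicate sensitivity samples and distribution plots,
validation reports and scatter plots, and a `run_log.jsonl` stamped with
the configuration hash. On the seed-1 scenario the SER validation report
reads

```
n_plots,24
spearman_rho,0.8592331581756205
r_squared,0.7518636345001051
```

i.e. the 24 synthetic plots' observed erosion scores track the mapped
risk strongly (rho = 0.86), and the sensitivity stage reports both models
stable (all weight pairs distinguishable) at ±10 % perturbation.

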