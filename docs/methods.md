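# Methods

## Weight elicitation (AHP)

Pairwise judgments on the discrete 1/9…9 scale are assembled into a
positive reciprocal matrix with unit diagonal; only the upper triangle is
supplied and the lower triangle is forced to the reciprocals, so
reciprocity is exact by construction. Weights are derived by column
normalization followed by row averaging — for a perfectly consistent
matrix (a_ij = w_i/w_j) this recovers the generating vector exactly, and
it is the variant of AHP that pairs with the simple additive weighting
model used downstream. λ_max is taken as the exact dominant eigenvalue
(`numpy.linalg.eigvals`), not the common (A·w)_i/w_i approximation,
because the consistency index is defined through the eigenvalue; the
random-index table is Saaty's standard one (0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45, 1.49 for n = 1…10) and is an argument of
`consistency_ratio`, so other tables can be substituted. For n ≤ 2 a
reciprocal matrix cannot be inconsistent; CR is defined as 0. Judgment
values are not restricted to the discrete scale by default (elicitation
tools sometimes interpolate); a `strict_scale` flag enforces it.

Participant aggregation is the arithmetic mean of the individual weight
vectors, renormalized — each participant gets equal say regardless of how
extreme their judgments are. Geometric-mean aggregation of judgments is a
deliberate non-goal.

## Criterion layers

**Spectral.** Scene pairs are chosen around the fire dates with an
expanding time buffer (30 d initial, +15 d steps, 120 d cap, < 10 % cloud
cover); when several scenes qualify on a side they are composited by the
per-pixel mean of valid observations. NBR, dNBR and BSI are plain band
arithmetic with nodata wherever a denominator vanishes or an input is
nodata. The BSI is implemented in normalized-difference form,
((SWIR+RED) − (NIR+BLUE)) / ((SWIR+RED) + (NIR+BLUE)), which is the
standard formulation and the only one bounded in [−1, 1] as the erosion
threshold table requires. Severity classes partition the line:
unburned < 0.1 ≤ low < 0.27 ≤ moderate ≤ 0.66 < high. The same
boundaries, with the unburned and low classes merged into score 1, give
the gapless 1–3 severity scoring used by the recovery model.

**Terrain.** Slope and aspect use Horn's 3×3 finite differences; slope is
expressed in percent because every threshold that consumes it is stated
in percent. Aspect follows the universal GIS convention — the compass
direction of steepest *descent*, i.e. the direction the hillside faces —
which is what the insolation argument behind the aspect scores (south-
facing = most evapotranspiration = score 3) refers to. Flat cells have no
defined aspect; they are scored 1 (no insolation penalty), and the score
table is replaceable if a different treatment is wanted. Border cells are
nodata.

**Normalization.** Continuous erosion criteria are clamped linear
rescalings between expert thresholds: dNBR 0.1–0.66, K 0–0.55, BSI −1–1,
slope 9–80 %, resprouter cover 0–0.4 (i.e. saturating at 40 % cover,
beyond which early resprouting is taken to suppress erosion fully). The
resprouter layer is the only one with subtracted polarity.

**Vegetation.** Per polygon, `percent_resprouters` is the summed cover of
resprouter-strategy records and RC is the cover-weighted mean strategy
rank over up to three co-dominant tree species plus one shrub and one
grass record, hence a convex combination in [1, 3]; zero total cover is
an error rather than a silent default. Polygon attributes are burned onto
the analysis grid by cell-center membership — the conventional zonal
default, and exact for the tessellations the generator produces.

**Fire history.** The frequency sub-score counts overlapping burned areas
in a 20-year window (≤1 → 1, 2 → 2, >2 → 3) and the immaturity sub-score
uses the time since the last fire (>15 y → 1, 10–15 y → 2, <10 y → 3).
The combined score defaults to the maximum of the two — either hazard
alone is taken as sufficient — and an explicit 3×3 combination matrix can
be supplied where a different local calibration exists.

## Composites

Layers are co-registered to a common 10 m grid over the intersection of
extents (bilinear for continuous, nearest for categorical layers, so
class codes are never invented). The two indices are elementwise weighted
sums masked to the burned perimeter. SER mixes [0, 1] layers and
subtracts the resprouter term, so its theoretical range is
[−w_PR, 1 − w_PR]; negative values (resprouting outweighing all hazards)
are retained and the range is recorded on the map object rather than
rescaled away. VRP is a convex combination of 1–3 scores. The two indices
deliberately keep their native scales — each is internally consistent and
the banded (low/moderate/high) maps use equal intervals over the
theoretical range (quantile banding available, erroring on constant
maps). Note the orientation: *higher* VRP means *slower or poorer*
expected recovery, since every input scores 3 for the least favourable
condition; the name is kept for continuity with the weighting exercise
and the orientation is documented rather than inverted.

## Monte-Carlo sensitivity

Each replicate multiplies every weight by an independent uniform factor
in [1−p, 1+p] and renormalizes; p ≥ 1 is rejected since weights could
become nonpositive. Uniform sampling is the default law (a truncated
normal would also be defensible; uniform is the most conservative given
only a ± range). Summaries: the fraction of replicates preserving the
nominal importance ordering, and per pair the fraction of replicates in
which the two criteria swap order — a numeric stand-in for the visual
overlap of weight-distribution plots. Two distributions count as
distinguishable when that fraction is below 0.25 (configurable); the
stability report returns the largest perturbation level at which all
pairs remain distinguishable, with downward closure enforced (instability
at a lower level disqualifies higher ones). Defaults: 1000 replicates at
p ∈ {0.1, 0.2, 0.3}; a seed is required in the CLI.

## Field validation

Plot erosion intensity is the maximum of the per-type scores
(NE 0, EDD 0.2, EDF 0.4, EO 0.5, XDD 0.6, XDF 0.8, ESF 0.9); taking the
maximum records the most severe process observed anywhere in the plot.
Vegetation recovery is the height-weighted cover volume proxy
1.20·shrub_cover + 0.10·grass_cover (covers as fractions, heights in m);
it is deliberately unnormalized — an absolute volume-like quantity —
because only rank association with the maps is claimed. Standing trees
are excluded to focus on early-successional vegetation. Maps are sampled
by the mean of valid cells whose centers fall within the 10 m plot
buffer; partial-cell area weighting is not used (at 10 m cells it would
change means by less than the cover-estimation error). Statistics:
Spearman with average ranks, OLS observed~predicted, one-way ANOVA by
locality and by impact category on both the regression residuals and the
raw observations (the residual version asks whether the *model errors*
differ by group; both are reported since either reading is defensible),
plus Shapiro residual-normality and Levene homoscedasticity diagnostics.
Constant inputs flag the correlation undefined while the regression is
still attempted.

## Synthetic scenarios

The generator emulates every input at desk scale: a 96×96 10 m analysis
grid (192×192 at 5 m for the DEM), a smoothed Gaussian random-field DEM
(60 m relief, 80 m correlation length) with a gentle tilt so flat-aspect
cells are rare; an elliptical burn scar whose interior dNBR is
rank-sliced into a configurable low/moderate/high severity mixture
(default 30/45/25 %) and realized by shifting the NIR/SWIR balance of the
post-fire stack, with RED/BLUE raised with burn intensity so BSI responds
too; a rectangular vegetation tessellation whose per-strategy covers are
Dirichlet-distributed around configured mean covers (default 35 %
resprouter, 30 % post-fire seeder, 25 % seeder of each polygon); an
erodibility field in [0.05, 0.55]; an aridity gradient spanning all three
score bands; historical fire perimeters including one outside the 20-year
window; five participants whose judgment matrices are weight ratios
(drawn around a common prior, so participants differ in strength but
broadly share an ordering) snapped to the Saaty scale — all CR < 0.1 by
construction; and two field localities with 11 and 13 plots whose
erosion codes increase stochastically with the true SER at the plot and
whose shrub/grass covers decrease with the true VRP (noise levels 0.15 by
default). Plot locations are spread across the within-perimeter SER range
so validation is not leverage-starved.

Every product draws from its own seeded child generator, so outputs are
byte-identical per (seed, parameters) and regenerating one product never
perturbs another. What the generator does *not* emulate: atmospheric and
sensor effects, cloud geometry (the catalog's cloudy scenes are decoys
with a cloud fraction only), understory vegetation missing from forest
maps, spatial autocorrelation of field-crew error. Passing tests
therefore demonstrate the pipeline's internal correctness and its
sensitivity/validation machinery, not remote-sensing realism.

## Numerical choices and degenerate inputs

Reciprocity and unit diagonal are enforced to 1e-9; weight vectors must
sum to 1 within 1e-9. Severity and score tables are checked to cover
their domain (a value outside any interval is an error, never a silent
class). dNBR at a zero NIR+SWIR denominator is nodata, and nodata
propagates through every elementwise and resampling step (a bilinear
neighbourhood containing nodata yields nodata). Tie handling: nominally
tied weights count as never distinguishable in the sensitivity overlap;
Spearman uses average ranks. Erosion scores with 24 plots and 7 discrete
levels necessarily tie, so even noise-free observations give rho slightly
below 1 against a continuous index; tests assert the tie-aware property
(monotonicity of scores in the true index) instead of rho = 1.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 96×96
default grid (seconds per run), 10 000-replicate weight-only Monte-Carlo
studies, 100 random 64×64 grids for composite properties, and 20-seed
field-validation campaigns. These sizes were chosen as the smallest at
which the spatial stages (alignment, rasterization, buffer sampling) are
non-trivially exercised and the stochastic summaries are stable.

## Known limitations

Additivity and linearity are assumptions of the weighting model itself;
interactions between criteria (e.g. severity × aridity) are not
representable. The erosion-threshold table and score tables are regional
expert calibrations shipped as overridable defaults — transferring the
method to another region requires re-elicitation and re-validation. The
raster container supports square-celled, north-up grids in a projected
CRS only; geodetic rasters must be projected upstream. GeoTIFF I/O is not
provided; ESRI ASCII grids are interchangeable with it in any GIS at
these grid sizes.
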