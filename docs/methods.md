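# Methods

This note documents the models and procedures implemented in `occutrait`, the
choices made where the design was genuinely open, and what the synthetic
worlds do and do not establish about real biological-records data.

## Data model

The unit of observation is a (1 km²-analogue pixel, year) sample. Two record
types are supported:

* **full-list** surveys: every species of a group is looked for, so recorded
  absences are meaningful (if noisier than presences);
* **presence-only** records: only detections are reported. For these, every
  site-year holding at least one record of the group becomes a sample, and the
  presences of the other group members act as pseudo-absences for the focal
  species.

Species with fewer than 30 presences over the study window are dropped before
table construction (default `min_records=30`, configurable). Traits are
standardised within each group (zero mean, unit SD) because trait measurements
are not comparable across groups; a zero-variance trait maps to 0 with a
warning. A flattened two-level taxonomy (one-hot subclade membership) is
appended to the trait vector so the shared network can pick up trait-like
structure aligned with relatedness that measured traits miss.

Class weights per species are `w0 = (n0+n1)/(2 n0)`, `w1 = (n0+n1)/(2 n1)`
(linear), or their square roots. Defaults follow record type — linear for
presence-only groups, square-root for full-list groups — and are overridable.
Two conventions the weight definition leaves open: a species with no absences
gets `w0 = 1` with a warning, and a species with no presences is an error
(it should have been filtered).

Latitudinal regions are lower-inclusive/upper-exclusive slices of northing; a
coordinate exactly at a cut joins the upper slice. The train/test split is
stratified by (group, year) with `test_fraction=0.25` by default; singleton
strata go to train with a warning.

## Community model

Each community model averages two networks on the probability scale:

    p_s(d) = 1/2 [ sigmoid(shared(d, t_s)) + sigmoid(species(d)_s) ]

The shared network (driver vector ⊕ trait vector → logit) is rigid — identical
parameters for all species — which is what lets it express trait-mediated
responses and lend rare species the stereotypical response of trait-similar
species. The species network (driver vector → one logit per species) is
flexible and captures idiosyncratic direct responses.

Both networks are trained **jointly** on the class-weighted binary
cross-entropy of the averaged prediction (weight-normalised), with full-batch
Adam, early stopping on a 10% validation sub-split (patience 20), and best
weights restored. Joint training was an open choice; we prefer it because the
averaged prediction is the quantity used everywhere downstream, so the
networks should be optimised for it as a unit. Output layers are
zero-initialised, so an untrained model predicts exactly 0.5; hidden layers
use He initialisation. Default sizes are 2×64 units per network (ReLU); the
reference studies use 2×16 (recovery) and 1×8 (null replicates), which are
ample for the synthetic worlds' logit-linear truth. Driver inputs are
standardised with training-set moments stored in the model. Training is
deterministic for a fixed seed and thread count.

Skill is the per-species Matthews correlation coefficient on the held-out
split, binarising at 0.5 (configurable); any zero factor in the denominator
gives MCC = 0 by convention.

## Bagging

Each of the 20 bags trains on an independent uniform 50% subsample of the
training pool drawn **without replacement**, so two bags share in expectation
half of each bag's training data. (A classic with-replacement bootstrap would
give ≈63% support overlap instead of the intended half.) Per-bag seeds derive
from the master seed via a counter-based `SeedSequence` scheme recorded in the
ensemble manifest. Aggregation uses linear-interpolation percentiles — 5/50/95
for predictions (the 90% PI) and additionally 25/75 for explanations. A bag
that fails to train aborts the run; bags are never silently dropped.

## Explanations

Attributions are single-feature interventional perturbations: for sample `x`
and driver `j`, φ(x) = p(x) − mean over 50 background substitutions of
`x_j`, backgrounds drawn from the empirical marginal of the driver in the
bag's own data. φ is then regressed (OLS) on the standardised driver value
across 50 random samples, giving one linear slope per (bag, species, driver).
This is deliberately *not* coalition-based Kernel-SHAP: the single-feature
perturbation is the procedure being characterised. Backgrounds are drawn
independently per (group, driver, bag); samples are shared across species
within a group.

Strength and consistency rules:

* direct effect, per group × driver × bag: strong positive if the 25th
  percentile of species slopes is > 0, strong negative if the 75th is < 0;
* mediation, per group × trait × driver × bag: species are split into trait
  terciles (equal sizes ±1, remainder to the low group, ties broken by stable
  order); strong if one tercile's 25th percentile exceeds another's 75th;
* consistency: the same sign (or same ordered tercile pair) strong in ≥15,
  ≥18, ≥19, 20 of 20 bags → 75%, 90%, 95%, 100%.

Groups with fewer than 4 species are excluded from direct-effect flags
(quartiles of 3 values are not meaningful); mediation needs ≥2 species per
tercile.

## Trends

Occupancy trend series are mean predicted (or observed) probabilities per
region-year, enveloped across bags. Random-location series re-predict at
uniform random pixels with per group-year counts matched to the test split —
under preferential sampling these are the more representative estimate of
regional change. Trait assemblages weight trait values by predicted
probability and max{MCC, 0}, per sample, then average unweighted over the
region-year's sample set; samples where all weights vanish are excluded with
a warning.

Trend marking fits OLS on year, applies a two-sided *t* test with Bonferroni
adjustment (`n_comparisons` defaults to the number of series plotted together,
configurable) at α = 0.01, **and** requires the absolute effect to exceed an
effect-size floor per decade: 0.01 probability for occupancy, 0.01–0.02 trait
SD for assemblages. Both conditions must hold; a minute but ultra-precise
slope is deliberately not flagged.

## Local causes of change

Per pixel and driver, the rate of change is the OLS slope of the driver value
on year. Multiplying by a community-level effect per driver (median over
species of the bag-median slope; mean available) gives an impact in
probability/year; the driver with the largest positive (negative) impact is
the pixel's leading positive (negative) cause, with 2nd and 3rd ranks also
emitted and coverage shares reported per driver. Effects are treated as
spatially constant; ties break by impact magnitude then stable driver order.
Aggregated effects produce one map (rather than per-bag maps aggregated
afterwards) — the cheaper and more interpretable of the two open options.

## Synthetic worlds

The generator's truth model is logit-linear with product interactions:

    logit p_s(x, y) = baseline_s + Σ_j (β_j + Σ_m γ_jm t_sm) · d_j(x, y)

This is the minimal generative structure under which "trait mediation" is a
well-defined, recoverable quantity; the real analysis assumes no generative
model, so this is a deliberate idealisation. Driver fields are kernel-smoothed
Gaussian noise (smoothing scale 3 pixels by default) mixing a static field
with yearly anomalies (80% persistent variance), standardised over all
pixels-years, with configured linear trends added in SD/year. Sampling is
preferential: site visits ∝ exp(bias_south · southness), yearly effort ∝
exp(bias_time · year index); defaults (1.0, 0.04) emulate southern-heavy
recording that roughly triples over three decades. Detection of a true
presence at a visited site is Bernoulli(0.9) by default; full-list groups
record non-detections as absences, presence-only groups record nothing.
Baseline logits are N(−1, 1), i.e. mean occupancy near 0.27.

Reference studies (`occutrait.worlds`):

* **recovery world** — 20×20 grid, 31 years, 6 drivers, 3 groups × 10
  species (one full-list), 3 traits; β = (0.5, 1, −1, 0, 0, 0), γ = 0.8 on
  (driver 0, trait 0), driver-0 trend +0.03 SD/yr; 60 expected visits/year;
  20 bags of 2×16-unit networks.
* **null world** — 12×12 grid, 12 years, 2 drivers, 12 species, γ = 0;
  50 replicates of 20 bags of 1×8-unit networks measure the mediation
  false-flag rate.

Problem sizes were set so the recovery study runs in under a minute and the
50-replicate null study in a few minutes on one CPU.

What the synthetic worlds do **not** emulate: real coastline or land masks
(full rectangular grids only), realistic driver covariance structure or the
BIOCLIM metric definitions, abundance (occupancy probability only),
weather-dependent recorder behaviour (little is quantitatively known about
it), and misidentification error. Passing recovery tests therefore shows the
pipeline is statistically sound under its own assumptions — not that real
trait mediations of this kind will be detectable at a given survey intensity.

## Numerical conventions

* Percentiles everywhere by linear interpolation (numpy default), stated for
  cross-language reproducibility.
* Probabilities clipped at 1e−7 in the cross-entropy; MCC zero-denominator →
  0; zero-variance attribution draw → slope 0 plus a degeneracy flag.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` streams; world generation uses fixed stream
  indices per stage so results do not depend on call order.

## Known limitations

* The mediation test inherits the instability of quartiles over few species;
  with ~10 species per group, terciles of 3–4 species make the three-quartile
  rule conservative but occasionally jumpy — the bag-consistency ladder is
  what keeps the false-flag rate low (measured ≈6% at the 75% level in the
  null study).
* Traits that correlate with a truly mediating trait (or with species
  baselines) can legitimately show mediation signal; the scan reports all
  flagged pairs and leaves causal reading to the analyst.
* The numpy networks are full-batch and CPU-bound; they are sized for
  desk-scale synthetic communities, not for hundreds of thousands of records
  (the architecture, not the implementation, is the object of study here).
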