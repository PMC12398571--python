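# occutrait

Trait-mediated multi-species occupancy modelling for biological records.

`occutrait` is a research pipeline for ecologists who want to go from biased
species occurrence records (full-list surveys and opportunistic single-species
observations), a species trait table, and gridded environmental drivers to:

1. **bagged occupancy predictions** with 90% prediction intervals,
2. **linearised driver effects** per species from perturbation attributions,
   with consistency flags across bootstrap replicates,
3. **trait-mediation detection** — which species traits modulate which driver
   responses — via low/mid/high trait groupings,
4. **skill-weighted trait-assemblage trends** per region and year, and
5. **maps of the leading local drivers** of predicted occupancy change.

Because real national recording-scheme data are access-restricted, the package
ships a first-class synthetic-community generator with known ground truth
(implanted driver effects and trait mediations, preferential sampling in space,
time and taxonomy), so that every stage of the pipeline is testable end to end.

## The model

Occurrence records are converted to presence–absence contingency tables at the
pixel–year level; for presence-only groups, presences of other species in the
group serve as pseudo-absences. The resulting class imbalance is compensated by
species-specific class weights

$$w_0 = \frac{n_0+n_1}{2n_0}, \qquad w_1 = \frac{n_0+n_1}{2n_1},$$

which equalise the total loss mass of presences and absences (linear weights;
their element-wise square roots are used for full-list groups).

The community model is an ensemble of two feed-forward networks whose
probability-scale predictions are averaged,

$$p_s(d) = \tfrac12\left[\sigma\big(f_\text{shared}(d, t_s)\big) + \sigma\big(f_\text{species}(d)_s\big)\right],$$

where $d$ is the driver vector and $t_s$ the trait vector of species $s$
(including a flattened-taxonomy one-hot block). The shared network applies the
same parameters to every species — trait mediation of driver responses lives
here, and rare species borrow strength from trait-similar common species — while
the species network captures species-specific direct responses. Models are
bagged (20 half-overlapping training subsets) to quantify data uncertainty.

Driver effects are estimated per bag by a single-feature interventional
attribution, $\phi_s(x) = p_s(x) - \mathbb{E}_b\,p_s(x \mid x_j{:=}b)$, with 50
random samples and 50 background draws, then linearly regressed on the driver
value to give one slope per (bag, species, driver). A group-level effect is
*strong* when the species-slope distribution excludes zero by three quartiles,
and a trait mediation is *strong* when two trait terciles exclude each other by
three quartiles; strength in ≥15/18/19/20 of 20 bags maps to 75/90/95/100%
consistency.

Trait assemblages weight each species' trait by its predicted occupancy and its
held-out Matthews correlation coefficient,

$$\bar t_y^r = \frac{1}{|X|}\sum_{x\in X}\frac{\sum_s t_s\, p_{s,x} \max\{\mathrm{MCC}_s, 0\}}{\sum_s p_{s,x} \max\{\mathrm{MCC}_s, 0\}},$$

and linear trends are marked significant only if a Bonferroni-adjusted
two-sided *t* test passes at α = 0.01 **and** the absolute effect exceeds 1%
probability (or 1–2% trait SD) per decade.

## Worked example

The reference "recovery world" implants a strongly positive (`driver_1`,
β = +1) and a strongly negative (`driver_2`, β = −1) direct effect, and a
warming driver (`driver_0`, trend +0.03 SD/yr) whose effect is positively
mediated by `trait_0` (the voltinism analogue):

```python
import occutrait as ot

study = ot.run_recovery_study(seed=7)
print(study.flags[study.flags.consistency != "none"])
```

```
 group   driver  median_slope direction consistency
     0 driver_1      0.139906  positive        100%
     0 driver_2     -0.152621  negative        100%
     1 driver_1      0.138453  positive        100%
     1 driver_2     -0.152211  negative        100%
     2 driver_0      0.044057  positive         90%
     2 driver_1      0.133718  positive        100%
     2 driver_2     -0.150905  negative        100%
```

Both implanted direct effects are recovered with the correct sign at 100%
consistency in all three groups (the mediated warming driver also surfaces
where its group's trait mix leaves a net positive effect). The mediation scan
finds the implanted (driver_0 × trait_0) interaction in all groups at 20/20
bags:

```
 group   trait   driver  n_strong_bags consistent_level
     0 trait_0 driver_0             20             100%
     1 trait_0 driver_0             20             100%
     ...
```

and the downstream summaries recover the warming phenomenology:

```
predicted voltinism-assemblage slope: +0.0082 / yr
true assemblage slope:                +0.0070 / yr
warming driver leads positive change on 75% of pixels
```

i.e. the skill-weighted community mean of the voltinism-like trait rises in
step with the truth model, and the warming driver is the leading positive
local cause of change on most of the map.

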