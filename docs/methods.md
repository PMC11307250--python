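# Methods

## The QSRR model and its assumptions

Retention of compound *i* under a condition *c* (stationary phase × organic
modifier) at time point *t* is modeled as a single-layer sigmoid network on
max-normalized molecular descriptors:

    k̂′_i = σ(w(c,t) · x_i + b),   σ(z) = 1/(1 + e^{-z})

fitted to the condition's retention factors normalized by their maximum, by
full-batch gradient descent on mean squared error. One model is fitted per
(phase, modifier, time point, compound set); the input weights `w` are
extracted as signed descriptor-importance scores. The approach assumes

* retention factors are a monotone (sigmoid-squashed) function of a linear
  combination of descriptors — adequate for ranking descriptor influence, not
  a mechanistic adsorption model;
* descriptors arrive pre-computed (e.g. from a descriptor calculator) and are
  comparable after division by the per-column maximum absolute value;
* all compounds eluting under a condition are used for training — the model's
  purpose is interpretation of weights, not out-of-sample prediction, so
  there is no train/validation split.

A one-hidden-layer variant (logistic hidden units, per-input scores by the
connection-weights sum Σ_j w_in[i,j]·w_out[j]) is provided for sensitivity
analysis. The direct architecture is the default because thresholding scalar
per-descriptor weights presupposes exactly one weight per input.

## Normalization

Descriptor columns are divided by the maximum *absolute* value, mapping each
column into [−1, 1]. Several descriptor families are negative-valued
(charge-eigenvalue descriptors such as BCUTc-1l), and dividing by a signed
maximum would flip their sign or blow up for all-negative columns; a
`signed-max` mode is still available as a switch. All-zero columns are
returned unchanged and reported, never rescaled. Retention-factor targets are
divided by their (positive) maximum per training set.

## Training parameters

| parameter | default | rationale |
|---|---|---|
| epochs ("learning cycles") | 500 | the historical protocol the pipeline mirrors |
| learning rate | 0.05 | conservative full-batch rate; config-exposed |
| init scale | 0.1 | weights start in U(−0.1, 0.1) |
| loss | MSE | smooth, matches the continuous normalized target |

On studies of ~100 compounds × 226 descriptors the historical setting (500
cycles at 0.05) underconverges, which attenuates weights and blurs the
importance ranking. Importance, stability and benchmark analyses therefore
use the package's converged setting `CONVERGED_ANN` (learning rate 1.0,
10,000 epochs, init scale 0.01); at ~0.25 s per model on one CPU this is
cheap. Both settings are ordinary configuration; every model file records
the configuration and seed that produced it. Divergence (non-finite loss or
parameters) raises an error naming the learning rate; a fit whose final loss
exceeds its initial loss is flagged `non_convergence` instead of rejected.

## The synthetic-study generator

The generator emulates the structure of a year-long SFC column-aging study:
107 compounds, 226 descriptors, phases silica/BEH/diol × modifiers
MeOH / MeOH+H₂O / MeOH+NH₃, time points 0M…12M plus a post-regeneration
injection R, compound classes (acidic/basic/neutral/both in fractions
0.3/0.3/0.3/0.1), and per-condition elution probability 0.8 (which reproduces
a narrowed set of roughly half the compounds across three phases, as in real
multi-phase studies).

Retention is generated through the same link the network assumes,
`k′ = k_max·σ(w·x + b) + ε` with `k_max = 20`, dead time `t0 = 1.0` min
(`t_R = t0·(1 + k′)`), and `ε ~ N(0, 0.1)` on the retention-factor scale
(≈1–5 % of t_R for weakly retained compounds — injection-to-injection
variability). The bias centers the median pre-sigmoid activation at zero so
retention spans the responsive range of the link.

**Descriptor collinearity is part of the design.** Real descriptor tables are
strongly redundant: many columns are near-duplicates of a smaller number of
underlying size/charge/connectivity features. The generator draws 40
"distinctive" columns with independent variation (including the class-linked
counts `nAcid`, `nBase`) and assigns the remaining 186 columns to 30
correlated blocks (latent within-block correlation 0.9), with per-column
monotone transforms producing continuous, count-like, right-skewed and
strictly negative families. The 20 planted informative descriptors per
condition are always drawn from the distinctive pool, with magnitudes
`2.5·U(0.8, 1)` and random signs (`nAcid`/`nBase` positive at baseline:
acids and bases are retained on fresh –OH phases). This is deliberate: with
fully independent columns at n = 107 < p = 226 the minimum-norm estimator
caps weight-recovery correlation at √(n/p) ≈ 0.69, so importance planted on
an arbitrary column of an *independent* design is not recoverable — and
importance planted on a near-duplicate of other columns is not attributable
even in principle. Planting on descriptors that carry their own information
is the configuration under which ground-truth recovery is a well-posed
benchmark.

**Aging** is injected in weight space, not t_R space, reflecting the
interpretation of retention drift as changing stationary-phase interactions:
scheduled additive offsets per (condition, time point, descriptor), zero at
baseline. The stylized class-linked schedule drops the `nAcid` weight and
raises the `nBase` weight by 2.5 (one effect-scale unit) from 2M onward, so
acidic compounds lose and basic compounds gain retention; at R the offsets
shrink to half (an incomplete regeneration) unless configured otherwise.

What the generator does **not** emulate: chromatographic physics (gradients,
pressure, silyl-ether chemistry), peak shapes beyond a linear width-vs-t_R
pass-through, replicate injections, descriptor measurement error, and
collinearity *between* informative descriptors. Passing recovery benchmarks
therefore shows the pipeline is correct and well-calibrated under its own
assumptions; on real tables where key descriptors are mutually collinear,
importance attribution spreads across correlated descriptors and single-name
recovery cannot be expected.

## Stability statistics

* Percent shifts use the baseline injection as 100 %; bins on |shift| are
  lower-closed/upper-open ([0, 0.5), [0.5, 1), [1, 2), [2, 5), [5, ∞) %),
  resolving the overlap of conventional figure-legend endpoints.
* Weight SD across time points uses the population formula (ddof = 0,
  switchable); the post-regeneration point is included in the SD window by
  default.
* The stability limit is the *maximum* per-descriptor weight SD on a
  user-chosen reference condition (the most stable one, e.g. diol), then
  applied to all conditions; an explicit `--sd-limit` overrides it.
  Exceedance uses strict `>`.

## Regeneration evaluation

%-error is reported signed, positive when retention decreased after
regeneration. "Within tolerance" uses `|%-error| ≤ 2 %` (absolute: a
restored column should match in either direction); "effective" uses strict
`<` against the 0M→12M difference (a tie is no benefit). Compounds missing
any of the three required time points are excluded and reported.

## PCA of weight vectors

Column-centered (not scaled — weights share a scale by construction), via
SVD. Explained-variance fractions are singular values squared over total
centered variance. Sign convention: the largest-|loading| entry of each
component is positive, making scores, loadings and plots reproducible.
Condition similarity is summarized by Euclidean distances and nearest
neighbors in retained-component space; cluster count is reported
descriptively, not inferred.

## Evaluation against planted truth

Trained weights recover the planted vector only up to a positive scale
(target normalization and finite training attenuate them), so recovery
scoring first rescales by the least-squares attenuation factor
`a = ⟨ŵ, w*⟩/⟨w*, w*⟩` and then applies the 1.5 threshold. Precision and
recall are computed against the planted informative set; sign recovery is
checked on the informative coordinates.

## Numerical choices and degenerate inputs

* Logistic function evaluated in the numerically stable two-branch form.
* Ties in importance rankings break by descriptor name (documented, tested).
* `k′` computation rejects t_R < t0 as non-physical; generated retention
  factors are clipped at 0 after noise.
* Benchmarks and the pipeline derive per-model seeds deterministically from
  the run seed (kept below 2³¹); identical configuration + seed gives
  byte-identical weight files.
* Problem sizes used by the self-evaluation: 10 independently seeded studies
  at the default scale (107 × 226) for recovery; two conditions × eight time
  points × 10 seeds for drift detection; three conditions × 10 seeds for the
  clustering benchmark.

## Known limitations

* The 1.5 importance threshold is meaningful on the normalized training
  scale (or after rescaling to a planted scale in benchmarks); weights from
  under-trained models sit on a smaller scale and need the rescaling step.
* The limit-derivation rule (max SD on a reference condition) is one
  reasonable reading of "lowest stable SD as the limit"; the raw limit is
  settable directly for other conventions.
* With fewer compounds than descriptors the fitted weight vector is not
  unique; reported weights are the gradient-descent solution from a small
  random start, which is reproducible but architecture- and
  seed-convention-dependent.
* No replicate-injection averaging: each (compound, condition, time point)
  carries one record.
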