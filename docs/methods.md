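# Methods

## The optimizer

DDTPSO minimizes a black-box objective over a bounded box with a population
of `n_agents` agents, alternating between two update rules.

**PSO rule.** Per agent,

```
v ← w(t)·v + c1·r1 ⊙ (pbest − x) + c2·r2 ⊙ (gbest − x)
x ← clip(x + v)
```

with `r1, r2 ~ U(0,1)^d` per agent per iteration and a linearly decaying
inertia `w(t) = w_max − (w_max − w_min)·t/T` (defaults `w_max = 0.9`,
`w_min = 0.6`, `c1 = c2 = 2`).

**DTO rule.** Agents are ranked by current fitness. The worst
`⌈exploration_fraction · n_agents⌉` (default 70%) take the exploratory
*flying* update

```
v ← K3·v + K4·r1 ⊙ (x_best − x) + K5·r2 ⊙ (x_gbest − x);   x ← clip(x + v)
```

and the remaining best-ranked agents take the exploitative *swimming* update

```
x ← clip(x_best − K1·|K2·x_best − x|)
```

where `x_best` is the current iteration leader, `K1 = 2·u1·(1 − t/T)` and
`K2..K5 = u2..u5` with `u_i ~ U(0,1)` drawn per agent per iteration. The
shrinking `K1` moves the swimmers from coarse to fine exploitation as the
run progresses. Several DTO variants circulate in the literature; this
two-rule formulation was chosen because it is the canonical
swimming/flying split and every coefficient is configurable.

**Dynamic swapping.** The controller starts with DTO. When the best-so-far
fitness fails to improve by more than `swap_tolerance` (default 1e-8) for
`swap_patience` (default 5) consecutive iterations, it switches to the other
rule and resets the counter. The rationale is to spend budget in whichever
regime is currently making progress: DTO's swimming contraction exploits
quickly; PSO's memory terms recover diversity when DTO stalls. A pinned
`strategy="pso"`/`"dto"` turns the hybrid into the corresponding plain
baseline (used for the degeneration test, which checks trajectory equality
against an independently coded PSO).

**Numerical choices.**

- Positions are clipped to the box after every move; velocities are left
  unmodified by clipping.
- Global-best ties: first found wins, so runs are stable under seeds.
- Personal bests accept *neutral* moves (equal fitness updates the stored
  position). On piecewise-constant objectives — exactly what a binarized
  feature mask induces on the continuous box — strict improvement freezes
  the swarm once every agent sits on its plateau; accepting neutral moves
  keeps agents drifting across plateaus and measurably improves how often
  the selector reaches the exhaustive-search optimum. Strictly decreasing
  best-so-far bookkeeping is unaffected.
- Non-finite objective values are counted, logged at debug level, and
  treated as `+inf`, so the agent keeps its previous personal best.
- All randomness flows through one `numpy` generator seeded from the
  config; identical config + seed gives bit-identical trajectories.

Defaults (10 agents, 80 iterations) follow the study configuration this
package operationalizes; the acceleration constants use the conventional
`c1 = c2 = 2`.

## Binary feature selection

The selector runs DDTPSO on `[0,1]^d`. Each candidate is converted at
*evaluation time* (the continuous population is never overwritten by bits):

- transfer `F(s) = 1/(1 + exp(−10·(s − 0.5)))`, a steep logistic centered
  at 0.5 so the box midpoint is the selection boundary;
- binarize with the inclusive rule `bit = 1 ⇔ F(s) ≥ 0.50` (a component
  exactly at the center is selected);
- score with `fitness = α·err + (1−α)·selected_fraction`, `α = 0.99`,
  where `err` is the misclassification rate of a k = 5 nearest-neighbor
  classifier on the validation third, using standardized Euclidean distance
  over the selected columns only (standardization statistics fitted on the
  training third — no leakage). The all-zero mask receives a `+inf`
  sentinel rather than a forced random bit, keeping the landscape pure.

The α = 0.99 weighting is the standard wrapper objective in this
literature: error dominates, and the size term (0.01 per full feature set,
i.e. `0.01/d` per feature) breaks ties among equal-error masks toward
smaller subsets. k = 5 is odd to avoid vote ties. Fitness values are cached
per distinct mask within a run.

Data are split into stratified equal thirds (train/validation/test, per-class
sizes differing by at most 1); selection only ever sees train+validation.

## Classifier tuning

The same optimizer minimizes validation error over a hyperparameter unit
box. Decode rules: continuous parameters map affinely (or log-affinely) from
a coordinate in [0,1]; grids and categoricals bin the coordinate by
`min(floor(x·m), m−1)`. The default space tunes a small scikit-learn MLP
(log learning rate 1e-4..1e-1, hidden width {8,16,32,64}, log L2 strength
1e-6..1e-1, batch size {16,32,64}); any factory producing a fit/predict
object can be substituted. Training failures score as worst fitness. The
winning configuration is refit on train+validation and reported on the
untouched test third; k-fold evaluation (default k = 10, stratified) sums
confusion counts over folds before computing metrics (micro-averaging), so
the metric formulas are applied to one table.

## Augmentation

Only the three stated geometric ops are used: horizontal flip, vertical
flip, counter-clockwise 90° rotation. They generate the 8-element dihedral
group of the square, so each source image has exactly 7 distinct
non-identity variants. Variants are enumerated in a fixed order (base ops,
then compositions of increasing length, keeping only new group elements)
and cycled round-robin over source images until the class hits the quota
(default 4000). Only when the distinct pool is exhausted are exact
duplicates emitted, with a logged warning — with 56 source images the pool
holds 7·56 = 392 variants, so reaching 4000 necessarily duplicates; the
warning makes that explicit. Every augmented record stores its op chain and
source index, and replaying the chain reproduces the pixels exactly.

## Statistics

- **Metrics**: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  positive predictive value TP/(TP+FP), negative predictive value
  TN/(TN+FN), and F score TP/(TP + 0.5(FP+FN)). Zero-denominator ratios are
  reported as missing, never silently 0.
- **Run statistics** over M seeded runs: mean/best/worst fitness, standard
  deviation with the M−1 denominator (missing for M = 1), mean validation
  error, and mean selected *fraction* (count/d), which keeps subset-size
  magnitudes below 1 and comparable across dimensionalities.
- **Average error** is the misclassification rate (identical to the mean
  squared error of a 0/1 correctness encoding).
- **Descriptive statistics** use linear interpolation between order
  statistics for percentiles (the mainstream default; under heavily tied
  per-run values any convention collapses quartiles onto the median).
- **One-way ANOVA**: textbook sum-of-squares decomposition; p from the F
  distribution; zero residual variance reported as an infinite F with p = 0
  and a degeneracy flag.
- **Wilcoxon signed-rank** (one sample vs a theoretical median): zero
  differences dropped, midranks for ties; for n ≤ 25 the two-sided p is
  exact, computed by a polynomial-product dynamic program over all 2^n sign
  assignments (doubled ranks keep midranks integral); above that a normal
  approximation with tie and continuity corrections. Testing strictly
  positive per-run values against median 0 — the comparison design this
  harness reproduces — is statistically vacuous (the positive-rank sum is
  forced to n(n+1)/2: 66 for n = 11, 55 for n = 10, exact two-sided
  p = 2/2^n), but it is reproduced as-is because it is part of the report
  format.
- **Regression report**: OLS slope/intercept with standard errors, t-based
  95% intervals (n−2 df), R², and the slope F test.

scipy supplies distributions and rank utilities; the SS decomposition and
the exact signed-rank enumeration are implemented here and cross-checked
against `scipy.stats.f_oneway` / `scipy.stats.wilcoxon` in the tests (the
scipy routines are oracles, not the implementation).

## Synthetic data

`gen_feature_dataset` emulates pooled deep-feature tables: informative
columns are class-conditional Gaussians with unit within-class sd and class
means spaced `class_separation` apart; redundant columns are random
unit-norm linear combinations of the informative block plus Gaussian noise
(sd 0.1); noise columns are standard normal; columns are shuffled with a
recorded permutation and the ground-truth informative indices are returned.
The default fixture (200 samples, 5 informative + 3 redundant + 12 noise,
2 classes, separation 3, seed 7) is small enough for exhaustive-mask
oracles on 10-feature restrictions yet noisy enough that selection matters.

What it does *not* emulate: feature correlations induced by a real
convolutional backbone, heavy-tailed activations, class imbalance, or any
imaging physics (speckle, anatomy). Passing tests therefore demonstrate the
mechanics and calibration of the method, not clinical performance.

`gen_synthetic_images` produces class-textured grayscale images (class-
specific blob counts, an oriented ramp, and a horizontal gradient that
breaks flip symmetry so augmented variants are pixel-distinct).

## Problem sizes

The shipped tests and the acceptance script run at desk scale: 10 agents ×
80 iterations for optimizer checks, 10 seeded selection runs against a
2^10-mask exhaustive oracle, 2,000 null simulations for ANOVA calibration,
and 4,000 random-sign draws for signed-rank calibration. These sizes were
chosen so every result recomputes from scratch in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- The DTO coefficient laws follow one published formulation; other variants
  exist and will produce different (though qualitatively similar)
  trajectories.
- The stagnation-driven swap rule is one defensible reading of "dynamic"
  hybridization; per-agent or per-phase schedules are not implemented.
- The exhaustive oracle is only feasible to ~16 features; beyond that the
  dominance property is checked only on restrictions.
- Wrapper fitness uses a single train/validation split per seed, not
  cross-validated fitness; this matches the harness design but makes
  per-run error estimates noisier.
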