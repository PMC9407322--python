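# Methods

`jujubespec` is a toolkit for classifying defective dried jujubes (normal
NM, starch-head SH, mildewed MD) from visible/near-infrared diffuse
reflectance spectra. The real spectra the method was developed on are not
publicly deposited, so the package ships a synthetic generator that
reproduces the documented statistical structure of those data; every other
component operates on any tabular spectra with the same layout.

## Synthetic spectra

Each class has a smooth base curve

```
base_c(λ) = 0.08 + A_c · s(λ) · (1 − 0.10·G(λ; 890, 22) − 0.16·G(λ; 990, 28))
```

where `s(λ)` is a logistic rise centred at 680 nm with width 30 nm (the
"red edge"), the two Gaussians carve absorption valleys at 890 nm (C–H
third overtone) and 990 nm (O–H second overtone / moisture), and the rise
amplitudes `A_NM = 0.62 > A_SH = 0.50 > A_MD = 0.38` give the documented
ordering of class mean reflectance above 700 nm (normal brightest,
mildewed darkest, starch-head between). A sample from class *c* is

```
x_i = (1 + a_i) · base_c + b_i + ε_i
```

with multiplicative scatter `a_i ~ U(−0.15, 0.15)`, additive offset
`b_i ~ U(−0.02, 0.02)` (large enough that scatter correction measurably
helps), and band noise `ε_i` mixing a smooth correlated component
(Gaussian-filtered white noise, σ = 8 bands) with white noise at per-class
standard deviations (0.010, 0.018, 0.055). The mildewed level is set well
above the others because the fixed ±15 % multiplicative scatter contributes
*more* variance to the brighter normal class; 0.055 makes the mildewed
class's mean per-band dispersion the largest by a comfortable margin across
seeds, matching the described data where mildew degree varies strongly.
Default class counts are 200/302/98 (the study's imbalance), 934 bands over
400–1100 nm.

What the generator does **not** emulate: real absorption band shapes and
chemistry (no radiative transfer), wavelength-dependent instrument noise,
and inter-class correlation structure beyond amplitude ordering. Passing
tests on these data therefore demonstrate algorithmic correctness and the
direction of methodological effects (e.g. oversampling lifting minority
recall), not field performance on real fruit.

A note on the band count: the instrument axis is 1044 uniformly spaced
bands over 348–1141 nm; cropping that axis to 400–1110 nm retains exactly
934 bands, whereas 400–1100 nm retains 921. The generator's default range
follows the nominal 400–1100 nm; the cropping utility accepts any window.

## Stratified split

Per class, the training count is round-half-up of `count × fraction`; any
residual against the rounded overall total is absorbed by the largest
class. At 200/302/98 and fraction 0.7 this yields 140/211/69 training and
60/91/29 test samples. A single-sample class goes to training with a
warning.

## Multiplicative scatter correction

The reference is the column mean of the **training** spectra (kept fixed
for the test set to avoid leakage). Each spectrum is regressed on the
reference, `x = a + b·ref`, and corrected to `(x − a)/b`. The correction is
exact (machine precision) for affinely distorted copies of the reference
and idempotent on corrected data. Spectra whose slope magnitude falls below
1e−8 (essentially flat) are passed through unchanged with a warning.

## Oversampling

All four methods balance every class up to the majority count, treat each
minority class against the union of the others, and use k = 5 neighbours:

- **ROS** replicates existing minority rows at random.
- **SMOTE** interpolates `x_i + λ(x_nn − x_i)`, `λ ~ U[0,1)`, between a
  minority point and one of its k same-class nearest neighbours.
- **Borderline-SMOTE** (borderline-1) first classifies each minority point
  by its m = 5 all-class neighbours: all foreign → *noise*, at least half
  foreign → *danger*, else *safe*; only danger points seed interpolation,
  with partners drawn from the same class. If a class has no danger points
  the method falls back to plain SMOTE with a logged warning so the balance
  contract still holds.
- **ADASYN** allocates each minority point a synthesis quota proportional
  to its local difficulty (fraction of foreign points among its k all-class
  neighbours), then trims/pads the rounded quotas to exact balance.

Distances are Euclidean on the preprocessed feature space. Oversampling is
applied to the training set only, after scatter correction and before
wavelength selection.

## Wavelength selection

**CARS** runs N = 50 Monte-Carlo iterations. Each iteration fits a PLS
model (classification encoded as one-hot indicators, argmax decoding) on a
random 80 % calibration subset of the currently retained bands, with the
component count chosen by 5-fold CV on that subset (capped at
min(10, bands − 1)). Bands are weighted by the norm of their regression
coefficients across the class indicators. The retained count follows the
exponentially decreasing schedule `r_i = a·e^(−k·i)` with `a` and `k`
solved from `r_1·p = p` and `r_N·p = 2`; the top-weighted bands survive the
forced cut and adaptive reweighted sampling (weighted draws with
replacement) picks the final set. Each iteration's subset is scored by
5-fold CV misclassification of the PLS classifier; the lowest-error subset
wins, ties broken toward fewer bands.

**SPA** grows, from every candidate start band, a chain of minimally
collinear bands: each step adds the band whose projection onto the
orthogonal complement of the selected span has maximal norm (columns are
autoscaled first). Every chain prefix with 5–20 bands is scored by 5-fold
CV accuracy of an RBF-SVM; the best (accuracy, then fewer bands) wins.
Rank-deficient designs that cannot support the requested chain raise an
error.

## RSA and MRSA

The reptile search algorithm maintains N box-bounded candidates for T
iterations and rewrites every coordinate by a phase-scheduled rule (see the
`optimize` module docstring for the four rules and the R/ES/η/P operators).
Defaults follow the study: N = 20, T = 50, α = β = 0.1, ε = 1e−10.
Out-of-bound positions are clipped to the nearest bound. The best-so-far
solution is tracked greedily, so the fitness trace is non-increasing.

Two printed-versus-described ambiguities are resolved in favour of the
described behaviour, each with a flag restoring the literal form:

- the evolutionary sense is implemented as `ES(t) = 2·r3·(1 − t/T)`
  (decreasing over iterations) rather than the printed constant
  `2·r3·(1 − 1/T)`;
- `r3` is continuous uniform on [−1, 1] rather than an integer in
  {−1, 0, 1} (the integer reading collapses ES to three values).

MRSA differs from RSA in exactly two ways: the initial population comes
from a Tent chaotic sequence (first row uniform, subsequent rows
`z → 2z` or `2(1−z)`; the absorbing states {0, ½, 1} are re-seeded with a
fresh uniform draw since the orbit otherwise collapses), and after every
iteration each candidate is perturbed by a Gaussian random walk around the
current best — `Gaussian(Best, |τ|) + g1·Best − g2·x_i` with per-dimension
standard deviation `τ = (log G / G)(x_i − Best)` — accepted only if
strictly better. With both switches off MRSA reduces bit-for-bit to RSA
under the same seed, which the tests assert. τ is read as a per-dimension
standard deviation (the source leaves variance vs. SD and scalar vs.
vector unstated); `Gaussian(μ, 0)` returns μ exactly, so the walk of the
best individual is a pure attraction step.

GA (tournament 3, BLX-0.5 crossover at 0.9, per-gene Gaussian mutation at
rate 1/D with σ = 0.1 range, elitism 1) and global-best PSO (inertia
0.9→0.4, c1 = c2 = 2, velocity clamped to half the range) serve as
baselines at the same budget.

## SVM tuning and PLS-DA

The classifier is a one-vs-one RBF-SVM, kernel `exp(−g‖u−v‖²)`, with c and
g searched in [2⁻², 2⁸]². Features enter the kernel unscaled by default:
reflectance bands already share one physical scale, and per-band
standardization inflates squared distances to roughly twice the band
count, which drives `exp(−g‖u−v‖²)` to zero for every g in the stated box
as soon as more than a few dozen bands are kept (observed as a collapse to
near-majority voting at full scale). A `standardize` switch remains for
features on genuinely different scales, fit per CV fold to avoid leakage.
The tuning fitness is stratified 5-fold CV accuracy of the
training set; the fold assignment is derived once per tuning run and shared
across all fitness evaluations (common random numbers), so optimizer
comparisons are paired and the objective is deterministic for the
optimizer. Maximization is implemented by minimizing 1 − accuracy;
reported traces are converted back. Grid search over explicit (c, g) lists
breaks ties toward smaller c, then smaller g. PLS-DA regresses one-hot
labels on the spectra and picks the latent-variable count (1–15, capped by
what the data support) by 5-fold CV accuracy.

## Metrics

The confusion matrix uses the fixed class order (NM, SH, MD). Per-class
recall/precision/F1 come from one-vs-rest marginals; macro metrics are
unweighted class means (macro recall equals the mean per-class accuracy).
Undefined precision (zero predicted positives) is reported as 0 with a
warning so macro means stay defined.

Two kappa statistics are reported. `kappa_cohen` is standard Cohen's kappa
with chance agreement from the matrix's own marginals. `kappa_paper` uses
p0 = overall accuracy and chance agreement from pooling the K one-vs-rest
binary tables, `pe = (1 + (K−1)²)/K²` — for K = 3, pe = 5/9 and
`kappa = (9·p0 − 5)/4` regardless of the matrix's structure. This is the
convention under which all of the reference report's printed kappa values
(85.00, 87.50, 90.00, 91.25, 93.75) are exactly reproduced from their
accuracies; standard Cohen's kappa matches none of them.

Percentages are rounded half-up to two decimals only at the reporting
boundary; all internal arithmetic is full precision.

## Pipeline and reproducibility

`run_experiment` executes simulate/load → crop → split → MSC(train
reference) → oversample(train) → select bands(train) → tune → train →
evaluate(test). The split happens before MSC so the reference never sees
test rows (the alternative — correcting before splitting — would leak test
statistics into preprocessing). Every stage's seed is derived from the
master seed through a fixed `SeedSequence` spawn-key scheme, so toggling
one stage never shifts another stage's randomness and identical master
seeds give byte-identical metrics. Whether wavelength selection consumes
the oversampled or the raw training set is not documented in the source
material; the oversampled set is the default here (matching the flow
order), and the stage order is configurable.

## Problem sizes in the tests

The test suite exercises the full study geometry where it is cheap (the
600 × 934 generator, the 140/211/69 split, balance to 211/211/211) and
scaled-down simulations where model fitting dominates: CARS recovery uses
150 × 30 matrices over 20 seeds, the optimizer benchmarks use the study's
20 × 50 budget on 2-D test functions, and the end-to-end paired comparison
of oversampling uses half-scale class counts (100/151/49) with 60 bands
and a small (c, g) grid. These sizes were chosen so the whole suite runs
in about a minute and a half while keeping every assertion at the
documented study conditions that matter (class ratios, k = 5, the 7:3
split, the [2⁻², 2⁸]² box).

## Known limitations

- The generator's classes are separable mainly by amplitude; real spectra
  differ in band shapes and chemistry, so absolute accuracies on synthetic
  data do not transfer.
- CARS assumes a PLS linear proxy ranks bands usefully for a nonlinear
  SVM; this mirrors the reference procedure but is a heuristic.
- RSA's update rules divide by `Best + ε`; when the optimum lies exactly at
  the origin several rules degenerate gracefully (clipped) but the search
  on such problems is easier than the general case.
- ADASYN's exact-balance trim/pad slightly departs from the original
  formulation, which leaves rounding slack; it was chosen so all four
  oversamplers satisfy the same balance contract.
- In very high dimension the synthetic classes separate cleanly enough
  that a minority class may contain no "danger" points at all, in which
  case borderline-SMOTE takes its documented fallback to plain SMOTE; its
  distinctive danger-seed path is exercised by lower-dimensional
  constructions in the tests.
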