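# Methods

## Problem setting

The package models a dwarf-plantation growth survey: `n` sample plots,
each with plot-mean canopy reflectance in five bands (450, 550, 660, 750,
840 nm, fractions in (0, 1)) and four simultaneously measured growth
indicators — SPAD (unitless chlorophyll-meter reading), plant height
(m), leaf area index (dimensionless) and above-ground biomass (treated as
grams of oven-dry mass per tree; the unit cancels everywhere because only
normalised values and coefficients of variation enter the analysis).

## Composite index

Indicators are min–max normalised over the full dataset (`U_i ∈ [0, 1]`,
observed extrema map to 0 and 1). This is the direct use of the observed
range; it leaks the indicator extrema into any later train/test split, a
property shared by the protocol it reproduces and documented here rather
than silently changed. CGMI₁ is the equal-weight mean of `U_1..U_4`;
CGMI₂ weights each indicator by its coefficient of variation.

Two disambiguations in the CV weighting were genuinely open:

* **CVs are computed on the raw indicator columns, not the normalised
  ones.** Min–max scaling destroys the mean that the CV is relative to;
  CVs of scaled columns would give grossly different weights, while raw
  CVs renormalise to weights of the magnitude the protocol reports
  (≈ 0.13 / 0.24 / 0.30 / 0.33 for SPAD / PH / LAI / AGB).
* **SD uses the population convention (ddof = 0) by default**, with a
  `ddof=1` switch. At n = 66 the weights differ by < 1e-3 between the
  conventions, so nothing downstream depends on the choice.

## Vegetation indices

Twelve broadband indices are registered. Four of them (MSR, CI_red-edge,
MNVI, MTVI) circulate in typographically damaged forms in parts of the
applied literature (dropped exponents, shifted parentheses). The default
`literature` mode evaluates the canonical definitions from the indices'
original sources; `as-printed` mode evaluates the damaged strings
literally where they parse (MSR, CI_red-edge, MNVI) for auditability, and
falls back to canonical where they do not (MTVI). Each index carries a
runtime-retrievable provenance flag. Division by zero raises with the
offending plot named; it cannot occur on generator output because
reflectances are bounded away from the singular sets.

## Synthetic data generator

One latent "vigor" scalar per plot (standard normal) drives everything:

* **Indicators**: `loading·vigor + Gaussian noise`, standardised
  analytically and mapped to target moments (SPAD 40.18 ± 3.75,
  PH 1.18 ± 0.20 m, LAI 2.90 ± 0.63, AGB 6348 ± 1516), so population
  moments are exact and sample moments carry the usual √n error. Default
  noise SDs (0.78, 1.88, 0.86, 0.53 in latent units) order the
  indicator–vigor correlations as canopy spectra see them: biomass and
  LAI strongly, SPAD moderately, height weakly (height is the least
  spectrally visible trait).
* **Reflectance**: linear in vigor with Gaussian noise, clamped to
  (0.01, 0.99); a configuration whose clamping affects > 10 % of samples
  is rejected as unphysical. NIR rises and red falls with vigor.

Band baselines/slopes/noises were calibrated once, by pilot simulation,
to the correlation structure the analysis assumes: the chlorophyll- and
structure-sensitive indices track CGMI₂ at |r| ≈ 0.6–0.85 with TCARI
strongest (mean r ≈ 0.82 over seeds). Two calibration choices deserve
note. The red baseline is 0.18 because ∂TCARI/∂R changes sign near
R ≈ 0.11: with a darker red baseline, TCARI *anti*-correlates with vigor.
The green band gets a small positive vigor slope (green-peak behaviour
of denser canopies); with a negative slope TCARI cannot lead the index
ranking. Known limitation: CI_red-edge plateaus near r ≈ 0.5 — under a
single latent factor the 750 and 840 nm bands are nearly proportional, so
their ratio carries little signal; pushing it into the 0.6–0.8 band would
require an unphysical red-edge model.

What passing tests on this generator do **not** show about real data:
there is no spatial autocorrelation between plots, no multi-date
phenology, no sensor calibration drift, and the indicator cross-
correlations arise from exactly one factor. Model rankings on synthetic
data are therefore directional evidence only.

## Screening

Pearson r with two-sided p-values (t transform, n − 2 df, via
`scipy.stats.pearsonr`). Model inputs are the k = 5 indices with largest
|r| against CGMI₂ among those with p < 0.01; ties break by registry
order. The full pairwise index–index correlation matrix is reported so
users can audit redundancy — no automatic collinearity elimination is
attempted. A `paper_protocol` switch fixes the five canonical inputs
(TCARI, CI_red-edge, OSAVI, DVI, MNVI) independent of the data.

## Models

MLR, PLS (2 components), SVR and RF delegate to scikit-learn with the
protocol hyperparameters. The SVR "kernel parameter 30" is interpreted as
a kernel *scale* σ (MATLAB convention), i.e. `gamma = 1/σ²`; ε defaults
to 0.01 on the [0, 1]-scaled target. On features of order 1 this kernel
is nearly linear and SVR is accordingly the weakest model — reported,
not tuned away. The RBF network follows the classic incremental
construction: starting from the mean predictor, the worst-fit training
point becomes a new Gaussian center (activation 0.5 at distance = spread,
spread 100 on min–max-scaled inputs), output weights refit by least
squares, until the MSE goal or a center budget of min(n_train, 25).

The BPNN is a natively implemented 5–12–1 network, tanh hidden layer,
linear output, parameters exposed as one flat vector of length
D = 5·12 + 12 + 12 + 1 = 85. Training is damped Gauss–Newton
(Levenberg–Marquardt) on the residual vector: λ starts at 1e-3, ÷10 on
accepted steps, ×10 on rejected ones, stop at MSE ≤ 1e-4, 1000
iterations, λ > 1e10 or a vanishing gradient. Random initialisation is
uniform [−1, 1], seeded. A mini-batch gradient-descent fallback honours
the protocol's learning rate 0.1 and batch size 9 (a batch size is
meaningless for full-batch L–M, so it lives in the fallback only).

**Early stopping.** By default 15 % of training rows are held out and
training stops after 6 consecutive rises of hold-out MSE, returning the
best-on-hold-out parameters. Rationale: with 85 parameters and ~50
samples, running L–M to the 1e-4 goal interpolates the training set and
generalisation collapses; the classic neural toolboxes apply exactly this
hold-out stop by default, and reported training errors in this protocol
family (train NRMSE ≈ 0.09) show the MSE goal is not what stops training
in practice. `val_fraction = 0` disables the hold-out and restores pure
goal/budget stopping (used by the exact-trainability tests). The hold-out
row choice is a pure function of (n, seed), so other stages can exclude
the same rows.

## Whale optimization algorithm

Standard three-branch scheme: with probability ½ an encircling step —
around the best agent when |A| < 1, around a uniformly random agent
otherwise (exploration; can be disabled for ablation) — else the
logarithmic spiral around the best, with `a` decaying linearly 2 → 0,
`A = 2ar − a` drawn per agent per iteration (r vector-valued per
dimension), l ~ U(−1, 1) per spiral use, spiral constant b = 1. Positions
clamp to the box. The leader updates greedily after each generation, so
the best-fitness trace (length T + 1) is monotone non-increasing — this
is asserted in tests on every run.

**WOA → BPNN wiring.** The search space is the flat parameter vector in
[−1, 1]⁸⁵ — matching tanh's active range on [0, 1]-scaled inputs; the
fitness is the raw forward-pass MSE (no inner training during the
search); the best position seeds L–M. The hold-out rows that L–M uses for
early stopping are excluded from the WOA objective too: no parameter
selection ever sees them. (Without this, the metaheuristic pre-fits the
validation rows and silently disables its own early stopping — in pilot
runs this reversed the comparison against the plain network.) The
architecture is fixed; only weights and thresholds are searched.

## Evaluation

Both R² conventions are always computed: the SSR/SST ratio form (which
can exceed 1 off the least-squares fit — the hand triple obs (1,2,3) /
pred (1,2,4) gives 2.5) and the conventional 1 − SSE/SST. NRMSE divides
RMSE by the *predicted* range by default (a flag offers the observed
range). MAPE is in percent and raises on a zero observation, naming the
row; batch reports use a non-strict mode that records NaN instead,
because a plot attaining the minimum of all four indicators has
CGMI₂ = 0 exactly. The split is a seeded uniform partition (52/14 at the
default n = 66). Summary tables round percentages to whole percent;
full precision is stored.

## Problem sizes

Defaults everywhere are the protocol scale: 66 plots, 52/14 split, WOA
10 × 60 (600 fitness evaluations of one forward pass over ≤ 52 rows),
sphere benchmark 30 × 500. The model-comparison medians in the
acceptance script use 10 replicate datasets; the directional
WOA-vs-plain comparison in the test suite uses 20. A full acceptance run
takes a few seconds on one CPU.

## Known limitations

* Absolute accuracies on synthetic data are not comparable to field
  studies; only orderings and directions transfer.
* The single-factor generator cannot produce indices that respond to
  different traits in conflicting directions (e.g. a structure index
  rising while a chlorophyll index falls).
* The ratio-form R² is reported for protocol fidelity but should not be
  used for model selection; the conventional R² is.
* Min–max normalisation bounds computed on the full dataset leak the
  extrema across the split (protocol-faithful; see above).
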