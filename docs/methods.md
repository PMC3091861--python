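# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices made where the problem left the design open.  It
states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

A panel is a long table of records (subject, procedure, time, mediator,
concentration) over 21 canonical analytes.  The design is cross-sectional:
each animal contributes one time point (destructive sampling), with
UNTREATED defined as time 0 and two treated arms (ST, ST_HS) at 1–4 h.
Loading enforces the hard invariants (nonnegative finite values, one value
per subject × mediator, one design cell per subject, UNTREATED ⇔ time 0);
`validate_panel` reports soft issues (missing baseline, n < 2 cells,
incomplete profiles) without raising.  "IL-12.total" is the canonical token
for total IL-12; an alias table absorbs the common synonyms
("IL-12p40/p70", "p40/p75", …) so no column is silently dropped.  Units are
never converted — every scale-sensitive step normalizes explicitly.

Transforms: `log_transform` is log10(value + offset) with offset 1.0 by
default (the smallest offset that maps 0 → 0 and keeps the transform
order-preserving on count-like concentrations); `max_normalize` divides each
mediator by its maximum over the chosen scope so values land in [0, 1], with
all-zero mediators mapped to zero rather than NaN.

## Synthetic generator

Concentrations are lognormal — the right-skewed, nonnegative character of
multiplex immunoassay data: value = m · exp(σu − σ²/2) with u standard
normal, so the arithmetic mean equals the configured m = baseline ×
fold-change(procedure, time).  Default σ = 0.5 (a coefficient of variation
of ~53%, typical of serum Luminex replicates); default baselines are round
numbers in the 10–200 pg/ml range per analyte.  Default group size is 6 per
design cell (54 animals total).

Cross-mediator correlation is planted per (procedure, window) through shared
per-animal latent factors — a Gaussian copula on the log scale: every member
of a block mixes a common animal factor with weight √ρ, giving pairwise
latent correlation ρ across the window's animals.  Because adjacent windows
share a bounding cell, a mediator may not sit in blocks of two adjacent
windows (same procedure); this is a validation error rather than a silent
averaging rule.  Negative ρ is supported for 2-mediator blocks (the only
case where a common factor can realize it exactly).  Baseline animals carry
no factors, since the 0–1 h windows of both procedures share them; planted
correlation in that window therefore acts on the 1-h cell, reinforced by the
activation mean-shift between the cells.

`study_mimic_config` encodes the qualitative study conditions: ST carries a
strongly correlated (ρ = 0.95) 4-mediator block in every window — early
chemokines, then interleukins, then IL-12/NO2−/NO3−, then TNF-α-centred
mediators — whose means rise across the window (3-fold at the first bounding
hour, 9-fold at the second).  The rising profile aligns the mean shift with
the latent factor, and the rise-then-fall of successive blocks keeps the ST
network dense in all four windows.  ST_HS is quiet for the first two hours
(no planted effects at 1–2 h), then activates late with staggered onsets:
MIG from 3 h and IL-12.total from 4 h (the planted discriminators) plus a
small KC/IL-10 block at 4 h.  Staggering matters: any two mediators that
jump at the same cell acquire a mean-shift correlation across the window, so
simultaneous onsets would create edges the design does not intend.

What the generator does **not** emulate: detection limits / floor effects,
plate or batch effects, heavy-tailed outliers beyond lognormality, and any
quantitative fit to the real study's group means.  Tests passing on these
panels show the pipeline recovers what was planted under idealized
lognormal noise; they do not certify performance on censored or batched
real-world panels.

## Univariate layer

- `pooled_t_test`: classical pooled-variance Student t, df = nA + nB − 2
  (10 at n = 6 per group; 46 when the four time points are pooled, 24 + 24 − 2).
  Degenerate inputs are resolved by convention: zero pooled variance gives
  t = 0, p = 1 for equal means and signed infinity, p = 0 otherwise.
  `t_from_summary` computes the same statistic from (mean, SEM, n) group
  summaries — the form in which per-group animal data are usually published —
  and is exactly equivalent because the pooled t depends on the data only
  through those summaries.
- The t-difference table uses the ST_HS − ST sign convention, per time point
  and pooled across times.  Raw p-values are reported; a Bonferroni column
  is emitted for transparency but never gates anything.
- `levene_test` is the classical mean-centered Levene W with the F
  reference.  That reference is asymptotic: at the study's n = 6 it is
  measurably liberal (empirical size ≈ 0.10 at α = 0.05 in the suite's
  simulation), which is a property of the test, not of the implementation;
  calibration is verified at n = 50.  `games_howell` pairs
  Welch–Satterthwaite df with the studentized-range distribution
  (k = number of groups).
- `anova_two_way` fits the balanced treated design (UNTREATED excluded,
  Time categorical) via OLS; with n per cell the residual df is 8(n − 1)
  (40 at n = 6).  Unbalanced panels are rejected rather than silently
  reweighted.
- `trend_model_fit` codes Procedure 0/1 (ST_HS = 1) and Time by orthonormal
  linear/quadratic polynomial contrasts on the four equally spaced levels;
  when both quadratic terms are nonsignificant at α = 0.05 the model is
  refit without them and flagged `reduced`.
- The **baseline gate** (`baseline_altered_set`) compares a window's treated
  samples against the untreated group with the pooled t at level α.  For
  the 0–1 h window only the 1-h cell is tested (6 vs 6) — the baseline group
  itself is the window's other bound, and testing it against itself would be
  vacuous; later windows pool both bounding cells (12 vs 6).  The gate is
  monotone in α by construction.  On right-skewed lognormal nulls the
  pooled t at 12-vs-6 is mildly conservative, which the acceptance-level
  calibration test quantifies.

## Discrimination

`fit_logistic_mle` is Newton/IRLS maximum likelihood.  Predictors are
standardized internally for conditioning and the coefficients and their
covariance are mapped back to the concentration scale, so reported slopes
are per-pg/ml.  Perfect separation is detected (fitted probabilities at the
labels, or a diverging coefficient norm) and returned as a flagged fit with
the last finite coefficients and no Wald p-values — never an exception.
Wald z and p accompany each coefficient on converged fits.

`rank_single_mediators` ranks by the **likelihood-ratio** p of the
single-predictor fit rather than the Wald p.  The Wald statistic loses power
precisely when an effect is strong (Hauck–Donner: the estimated SE grows
faster than the estimate) and is undefined under separation, so it inverts
the ranking exactly where discrimination is best; the LRT orders those fits
correctly and degrades gracefully into the separated regime.  Both p-values
appear in the output table, with tier boundaries at 0.01 / 0.05 / 0.10.

`fit_pair_model` defaults to in-sample classification of all 48 treated
animals at cutoff 0.5 (`all_data`); `train80_test20` holds out
max(1, round(0.2n)) animals per procedure × time cell (1 of 6 at study
size), seed-controlled, and scores only the held-out animals.

The **hypergeometric null**: assigning n labels of each class uniformly at
random among 2n animals makes the correct count 2k with
k ~ Hypergeom(2n, n, n) — only even counts are achievable and the
expectation is n (24 of 48).  The exact pmf and upper tail calibrate any
observed success count.

`manova_wilks` computes Wilks' Λ per term (Procedure, Time, interaction) on
the balanced treated design with sum-to-zero coding, by comparing the error
cross-products of the full fit against the fit with the term removed
(Λ = det E_full / det E_reduced), and converts Λ to Rao's F approximation.
With one response this reduces exactly to the univariate ANOVA F, which the
suite asserts to 1e-8.

## Clustering

Animals are compared by Pearson correlation of their log10(1 + x) mediator
profiles, treated samples only (the untreated group is omitted):
d = 1 − r ∈ [0, 2].  Agglomerative clustering (average linkage by default;
complete and single available) uses the nearest-neighbor chain, whose tie
resolution depends only on input order, so runs are deterministic.  The
two-group cut is the root split, labelled 1/2 by descending size (ties: the
group containing the first sample).  Composition is tested by Pearson χ²
without continuity correction — appropriate at the 48-sample,
expected-count > 5 configuration — and the tree exports to a Newick-style
serialization with merge heights.

## PCA driver scores

PCA runs per procedure on that procedure's treated samples, max-normalized
within the subset (both scope choices are exposed).  Because normalization
equalizes ranges deliberately, the decomposition uses the **covariance**
matrix of the centered data, not the correlation matrix.  Components carry a
deterministic sign (largest-magnitude weight positive); variance fractions
e_i are taken over all components so scores are comparable across selection
rules (top-k, default k = 3, or minimal prefix reaching a cumulative
variance τ).  The driver score is S_j = Σᵢ |W_ij| e_i over the selected
components; the absolute value is required for a magnitude score since
loading signs are arbitrary, and makes S invariant to sign flips.

## Dynamic Network Analysis

Nodes of a window's network are the baseline-altered mediators (gate above);
edges connect node pairs with |r| ≥ 0.7 across the window's 12 animals
(raw concentrations by default; a log-scale flag is provided since skew can
attenuate raw-scale correlations).  0.7 is approximately the two-sided 5%
point of r at 12 samples (10 df).  Edges keep their sign — the threshold is
on |r| so strong negative coupling is drawn, not discarded.  A gated node
with (numerically) zero variance in the window stays a node but is flagged
and excluded from edges.  Density is D = 2E / (N_sig(N_sig − 1)), zero below
two nodes: normalizing by the *altered* node count means a window with many
perturbed but unconnected mediators scores low.  Central nodes are all
maximum-degree nodes (empty if no edges).  Monotonicity holds by
construction: raising the threshold never adds edges; lowering α never adds
nodes.

## Numerical conventions

- Zero-variance detection uses a relative floor (σ ≤ 1e-10 · max|x|):
  pivot/aggregation arithmetic leaves ~1e-13 residuals on constant columns.
- CSV round trips read with full float precision so write → load → write is
  byte-identical.
- All simulation entry points take an integer seed; identical seeds give
  byte-identical panels.
- Problem sizes in the test suite and acceptance script are the study's own
  (n = 6 per cell, 21 mediators), with recovery properties evaluated over
  100–200 seeded replicates and null calibration over 2000.

## Known limitations

- The gate and t tables test raw concentrations; detection-limit flooring,
  if present in real data, is not modeled.
- Games–Howell p-values rely on the studentized-range approximation with
  Welch df; at n = 6 they are approximate, as in any implementation.
- The mean-centered Levene test is liberal at n = 6 (see above).
- The generator's planted correlations are exact on the log scale; raw-scale
  Pearson correlations are attenuated by lognormality (noticeably for
  σ ≳ 1 or strong negative ρ), which is why the network builder exposes the
  log-scale option.
- The study-mimic preset is qualitative: it reproduces the designed network
  signature and discrimination structure, not any real panel's numbers.
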