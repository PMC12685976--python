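# Methods

This note documents the statistical procedures, the generative model behind
the synthetic studies, the numerical choices, and the design decisions made
where the design was genuinely open.

## Data model and conventions

Likert responses are integers in [−3, 3] with a 0 midpoint; pole
orientation is fixed once in the study design via the ordered scale labels
(first label → −3). "I don't know this item" is a first-class sentinel: the
literal string `NA` on disk, `pandas.NA` in a nullable-integer column in
memory — never a silently missing row, so row counts always reconcile
(rows in = records parsed + malformed rows reported). Multi-select age
responses store the selected bands of
`0-6, 7-17, 18-30, 31-50, 51-65, 66-80, 81+`; an empty selection is an
explicit outcome, distinct from unknown.

Eligibility bounds are inclusive on both ends (default 18–30 years): a
published range of 18–30 with both endpoints attested supports the
inclusive reading.

## Quality-control cascade

Stage order: word knowledge → straightlining → calibrator → control →
timing, each stage seeing only survivors of the previous stages. Choices
worth making explicit:

- All proportion thresholds are **strict** inequalities ("more than",
  "over"); boundary values are retained.
- *Word knowledge*: an item counts as unknown for a participant if any of
  its dimension responses is unknown; pseudoword controls never enter the
  denominator. Flag at proportion > 0.20.
- *Straightlining*: the statistic is the modal response's share of
  non-unknown responses per (participant, dimension) — a response must have
  been selected to be "the same response", so unknowns leave the
  denominator. Participant-level exclusion uses the 0.80 threshold counted
  over dimensions (word studies: excluded when more than 3 of the 5
  dimensions straightline; image studies: more than 2 of 4); the
  per-dimension removal uses 0.95. Both thresholds are config fields.
- *Calibrators*: a violation is a response whose sign is opposite to the
  calibrator's expected sign, at any magnitude; 0 and unknown are never
  violations; missing calibrator responses count as non-violations and are
  logged. Exclusion at ≥ 2 violations. Calibrators (item + expected sign)
  are declared per Likert dimension; the sign rule has no meaning for the
  checkbox age dimension, so it carries none.
- *Timing*: natural-log durations; per dimension the mean and SD are
  computed over the participants **entering the timing stage** (the cascade
  population — configurable to the full input population, since either
  reading is defensible). Fast = strictly below mean − 2.5·SD. Two or more
  fast dimensions exclude the participant; exactly one removes only that
  dimension's data. No upper cut-off. Zero SD (degenerate) flags nobody.
  Image studies use one whole-experiment duration, where a single fast flag
  excludes.

The first four filters are purely per-participant, so their flags are
independent of who else is in the sample; only the timing flags depend on
the stage population. The cascade report carries every decision with its
stage, and reconciles exactly: input rows = retained rows + rows removed
with excluded participants + rows removed as dimension blocks.

## Likert norms

Per (item, dimension): mean and sample SD (n−1 denominator, the convention
of norming datasets) over known responses treated as integers; counts and
proportions per scale point; Shannon entropy H = −Σ p log₂ p with
0·log 0 = 0. Entropy is reported in bits (base 2); any base is
monotone-equivalent. With zero known responses the statistics are missing
and counts are zero.

### Latent means (cumulative-link mixed model)

Arithmetic means ignore the ordinal nature of Likert scales and absorb
participant response bias. The latent mean instead comes from

P(y ≤ k) = logistic(c_k − u_item − v_participant), with six ordered
cutpoints and independent crossed Gaussian random intercepts. The marginal
likelihood over the q = I + P latent effects is maximised with a **Laplace
approximation**: log L ≈ ℓ_pen(b̂) + (q/2)·log 2π − ½·log det H(b̂), where
b̂ is the joint penalised mode and H the negative Hessian there. The inner
mode-finding problem is strictly concave (the ordered-logit log-likelihood
is concave in the linear predictor) and solved by damped Newton iterations
with an analytic sparse-structured Hessian; the outer problem over
(c₁, log cutpoint increments, log σ_item, log σ_part) uses L-BFGS-B with
finite-difference gradients, bounded log-σ in [−4, 3], and cutpoints
initialised from the empirical cumulative logits. The fit is deterministic
given data and settings. The logit link and Laplace approximation are the
defaults of the model family's standard software.

Item and participant effects are centred to mean zero (the common offset is
absorbed by the cutpoints); latent means are reported on the link scale and
used correlationally, not back-transformed to −3..3.

Correctness is checked against independent oracles in the test suite: the
likelihood derivatives against finite differences, and the Laplace marginal
log-likelihood against Gauss–Hermite quadrature of the exact
four-dimensional integral on a tiny crossed design (agreement to < 0.1 on a
log-likelihood of ≈ −40). Non-convergence raises an error carrying the
optimizer diagnostics; data with a single observed response level is
rejected (cutpoints unidentifiable).

## Age norms

Weighted coding: each known response distributes weight 1 uniformly over
its selected bands, or entirely to *no age* when nothing is selected.
Per-item weighted proportions divide the per-category weight sums by the
number of known responses, so they always sum to 1. The mode category is an
argmax with ties (within 10⁻⁹) broken uniformly by a caller-seeded
generator, recorded for reproducibility.

PCA is run on the items × 8 proportion matrix with **centred, unscaled**
columns: all eight columns live on the same [0, 1] proportion scale, so
variance standardisation is unnecessary (a correlation-PCA flag exists).
Explained-variance fractions are of the total variance over all eight
columns; because rows sum to 1 the centred matrix has rank ≤ 7 and the
fractions over all components sum to 1 with the last ≈ 0. Component signs
are arbitrary, so they are pinned by loading rules — PC1: 66–80 loading
negative (older = negative scores); PC2: 31–50 negative (middle-aged =
negative); PC3: no-age negative — matching the conventional
younger/older, middle-aged and no-age readings of the three components.

## Downstream analyses

- **Cronbach's alpha** per (list, dimension) with raters as the scale's
  "items": α = k/(k−1)·(1 − Σ var_rater / var_total), the orientation
  norming studies use for inter-rater consistency. Missing-data policy:
  raters missing more than half the list are dropped, remaining gaps are
  imputed with the item mean; both the orientation and policy are config
  arguments because neither is uniquely standard.
- **Correlation structure**: pairwise-complete Pearson correlations over
  items, with an |r| > 0.18 highlight set (configurable).
- **Cross-dataset correlation** through an explicit translation mapping;
  many-to-one translations are resolved by averaging (configurable); scale
  orientations are never auto-flipped, so a reversed scale shows up as a
  negative r rather than being silently corrected.
- **Ladenness** = |item mean| on the bipolar dimensions: distance from the
  neutral midpoint regardless of pole, for dimensions where no directional
  processing effect is expected.
- **Hierarchical regression**: two nested OLS fits on complete cases (rows
  missing any predictor of either step are dropped from both), raw
  (unstandardized) coefficients by default with a standardized report
  available separately. The R² change is tested with
  F(q, n − p₂ − 1) = (ΔR²/q) / ((1 − R₂²)/(n − p₂ − 1)); maximum VIF per
  step is reported. Zero-variance or collinear predictors raise errors
  naming the offenders. Predictors are used as supplied — in particular the
  frequency predictor must be log-transformed by the caller.

## Synthetic-data generator

The generator emulates the study conditions end to end so that the pipeline
can be validated against known ground truth.

- **Response model**: attentive participants answer item i on dimension d
  via P(y ≤ k) = logistic(c_k − a·θ_d(i) − b_p) with item locations
  θ ~ U(−3, 3), unit discrimination a, participant shifts
  b_p ~ N(0, 0.5²), and cutpoints (−2.5, …, +2.5) — the same family the
  latent-mean estimator fits, so parameter recovery is a fair test. Valence
  θ gets a +0.75 shift (clipped to [−3, 3]) to emulate the positivity skew
  of valence ratings.
- **Word knowledge** is drawn once per (participant, item) — known with
  probability 0.98 — and shared across dimensions, as not knowing a word is
  a property of the word, not of the question.
- **Age responses**: with an item-specific no-age propensity (Beta(1, 6))
  the selection is empty; otherwise bands are selected independently with
  probability proportional to the item's age profile (Dirichlet draws
  around young/middle/old/uniform archetypes), rescaled so the strongest
  band hits with probability 0.9, and a taken age branch always yields at
  least one band (a fallback categorical draw), keeping it distinct from
  the explicit no-age outcome.
- **Timings** are log-normal per dimension (ln duration ~ N(6, 0.35), i.e.
  ≈ 400 s per dimension block).
- **Attentiveness margins**: participants answer calibrator items on the
  calibrator's own dimension with a guaranteed expected-sign response
  (magnitude from {1, 2, 3}) and always mark pseudowords unknown. These
  margins are what make "every planted actor violates exactly its own
  filter, and no attentive participant violates any" a designed property
  rather than a high-probability event.
- **Bad actors** (each labelled in the ground truth): straightliners repeat
  one response on all Likert dimensions but stay attentive on calibrators
  and pseudowords; speeders log two dimensions 6 population-SDs below the
  mean log duration, with fast dimensions rotated across speeders so no
  single dimension's sample statistics are dominated by the outliers;
  calibrator violators flip exactly two calibrators (magnitude 2);
  pseudoword raters rate every pseudoword. There is no planted
  word-knowledge violator — attentive unknown rates (~2%) sit far from the
  20% threshold.

What the generator does **not** emulate: real lexical content and its
correlation structure across dimensions (items are synthetic labels with
independent θ per dimension), demographic effects on ratings (rater
demographics are independent of responses — which is what makes the null
check of the demographic profiles meaningful), list-to-list item
heterogeneity, and participant-specific cutpoint spreads. Passing tests
therefore demonstrate correctness of the pipeline's logic and estimators
under the stated model, not robustness to every feature of real data.

## Problem sizes and determinism

The reference validation conditions are 100 items × 60 participants for the
latent-mean benchmark (one dimension, ≈ 5,900 ratings — chosen as a
realistic single-list rating block), 200 participants for parameter
recovery, and 500 simulations of n = 2,000 items for the nested-F
calibration. Every stochastic component takes an explicit seed or
`numpy.random.Generator`; simulation outputs are byte-identical for a fixed
config and seed.

## Known limitations

- The CLMM assembles a dense joint Hessian over items + participants; it is
  comfortable up to a few thousand latent effects but is not built for
  norming studies with tens of thousands of raters in one model (fits are
  per-dimension and per-study, which keeps sizes moderate in practice).
- Laplace approximation bias is small for well-filled designs but grows for
  very sparse item/participant cells; no adaptive-quadrature fallback is
  provided.
- Removed data are never imputed; removals are terminal.
- The regression module fits linear effects only; quadratic ladenness
  effects are out of scope.
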