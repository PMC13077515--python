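# Methods

## Grading model

A response to a select-all-that-apply question is scored 1 iff the selected
option set equals the key's correct set exactly (set equality; no partial
credit), else 0. Option codes are opaque, case-sensitive tokens; whitespace
is trimmed on read and `;` is reserved as the in-cell list separator and
rejected inside codes. Questions flagged `requires_image` are excluded —
not scored — for models without multimodal capability; excluded records
carry a missing score and are dropped before every aggregate, so deleting
them from the input changes no output (a tested invariant).

Replicates are independent runs. Raw per-question accuracy is the mean of
the replicate scores. The failure rate of a group is the mean of
(1 − score) over its scored (question, replicate) cells, so failure and
accuracy are exact complements within any group. We deliberately average
over replicates rather than calling a question "failed" when any replicate
errs: this keeps failure = 1 − accuracy as an identity.

Two domain-accuracy aggregations are offered. The default,
`vignette_then_mean`, averages question scores within each vignette first
and then averages vignette-level accuracies unweighted (vignettes count
equally regardless of how many questions of the domain they contain);
`question_pooled` averages over all scored questions directly, which equals
the question-count-weighted mean of the per-vignette accuracies. The two
agree exactly on a single vignette, and pooled is kept because the raw
accuracy summary pools questions.

## The PrIME-LLM score

With k domain accuracies r_1..r_k placed at equally spaced angles, the
radar polygon's area is (1/2)·sin(2π/k)·Σ r_i·r_{i+1} (cyclic). Dividing by
the full-scale reference polygon's area gives

    S = (Σ_i r_i · r_{i+1}) / k,  r_{k+1} = r_1.

Properties (all property-tested):

- 0 ≤ S ≤ mean(r_i²) ≤ 1, with S = 1 iff all r_i = 1;
- uniform law S(a,…,a) = a²;
- weak monotonicity in each radius, strict when a neighbor is positive;
- balance reward: replacing adjacent (a, a) by (a+δ, a−δ) strictly lowers S;
- invariance under cyclic rotation and reversal of the domain order, but
  **not** under arbitrary permutation. The canonical order is the workflow
  order (DD, DT, FD, M, Q). Rather than hiding the adjacency dependence, the
  package records the order used on every output and exposes
  `order_sensitivity`, the min–max score over all (k−1)!/2 cyclically
  distinct orderings.

k = 2 is rejected (the polygon degenerates to a segment with zero area for
every profile). Vertices are drawn from the top, clockwise — a plotting
convention only; the score uses the closed form, which is start- and
direction-independent (verified against a shoelace computation to 1e−12).

Per-model summaries report mean, SEM (sample SD with the n−1 denominator,
divided by √R; reported as NaN for a single replicate) and min–max range
over replicates.

## Statistical suite

- Question-level accuracy across models: one-way repeated-measures ANOVA,
  model within-subjects, question as the repeated factor; classical
  univariate SS decomposition, no sphericity correction; constant data
  yields an undefined (NaN) F rather than 0/0. Post hoc: all-pairs paired
  t tests with Holm step-down adjustment. Zero-variance difference vectors
  are degenerate: identical columns give p = 1; a constant non-zero shift
  gives infinite t and an undefined p, logged.
- Replicate-level PrIME scores: one-way between-subjects ANOVA
  (df = (k−1, N−k)) with Tukey HSD contrasts via the studentized range
  distribution (simultaneous CIs; adjusted p verified against a 10⁶-draw
  Monte-Carlo null in the tests). The reported `p_raw` for a Tukey row is
  the unadjusted pooled-t p for the same contrast (q = t·√2), so
  p_adjusted ≥ p_raw always holds and the two coincide at k = 2.
- Planned two-group contrasts: both Welch and pooled-variance t tests are
  first-class via `variance_mode` — the two arise naturally and neither is
  privileged. Effect sizes: Cohen d on the pooled SD; Hedges
  g = J·d with J = 1 − 3/(4N−9); g's 95% CI from the normal-approximation
  variance (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)) (noncentral-t CIs are out of
  scope); CLES as the nonparametric pair-count estimator with ties counted
  one half (chosen over the normal-theory Φ(d/√2), which disagrees with the
  pair-count value on real data). cles(A,A) = 0.5 and
  cles(A,B) + cles(B,A) = 1 exactly.
- Question-level regression: Gaussian linear mixed model on per-question
  mean accuracy with fixed effects for question type (treatment-coded
  against the DT reference — configurable), age group, sex and the
  reasoning flag, and a random intercept per question. A singular fit
  (non-convergence, boundary variance, or a degenerate random-effects
  Hessian on tiny designs) is flagged on the result and the fixed effects
  fall back to the OLS solution rather than failing. A constant response
  short-circuits to the exact degenerate solution. Model-level regression:
  OLS with 95% CIs, p-values and R²; rank-deficient designs raise an error
  naming the collinear terms.
- All tests are two-sided with α = 0.05 by default (configurable). P-values
  are floored at 1e−300 — "beyond representable precision", never exactly 0.

Type-I error calibration of the ANOVA, RM-ANOVA and two-sample procedures is
verified by 2,000-replication null simulations (rejection rate within
0.05 ± 0.015).

## Synthetic benchmark generator

The generator emulates the structure the analysis assumes, not any specific
model's behavior:

    P(correct | m, q) = logistic(μ + α_m + β_d(q) + γ_q),  γ_q ~ N(0, σ_γ²)

with correctness drawn Bernoulli independently per (model, question,
replicate). A correct response selects exactly the key's correct set; an
incorrect one selects a uniformly drawn non-empty wrong subset — its
composition is immaterial downstream because grading only tests equality.

Defaults (chosen once as a realistic study scale):

| parameter | default | rationale |
|---|---|---|
| models × vignettes × questions × replicates | 21 × 29 × 9 × 3 (16,443 responses) | study-scale design |
| questions per vignette by domain | DD 2, DT 2, FD 1, M 2, Q 2 | plausible placeholder; per-domain counts per vignette are not published |
| baseline μ | 1.1 logits | pooled accuracy ≈ 0.7 |
| domain effects β (logits) | FD +1.4 > Q +0.6 > M +0.3 > DT −0.4 > DD −1.6 | reproduces the observed ordering: final diagnosis easiest, differential diagnosis hardest |
| abilities α_m | linspace(−0.9, 0.9) + 0.5 for reasoning models | ≥ 1.5-logit span so ranking is recoverable |
| reasoning / multimodal flags | 11 of 21 reasoning, 18 of 21 multimodal | study composition |
| question SD σ_γ | 0.8 logits | marked between-question heterogeneity |
| image fraction | 0.10 | minority of questions carry images |
| demographics | per-vignette age group (4 levels) and sex, fixed sampling weights | demographics attach to the vignette, not the question |

γ_q is per question (matching the regression's random intercept), not per
vignette. A single RNG stream seeded from `seed` and consumed in a fixed
(vignette, question, model, replicate) order makes outputs byte-identical
across runs.

What the generator does **not** emulate: free-text answers and the human
mapping onto options, prompt/context effects, within-model correlation
between replicates beyond the shared question difficulty, or miscalibrated
difficulty orderings. Passing parameter-recovery tests therefore shows the
estimators work when the assumed item-response structure holds; it cannot
validate the grading rubric or metric against real model behavior.

## Verification at scale

Problem sizes used by the test suite were chosen to keep the full run in a
few minutes on one CPU: the shoelace-identity sweep uses 10⁴ random
profiles; type-I calibration uses 2,000 null replications per procedure;
full-pipeline rank recovery runs on the default 21 × 29 × 3 benchmark at
seed 1 (Spearman ≥ 0.9 between true ability and mean PrIME score);
domain-effect sign recovery runs the mixed model on 100 independent default
benchmarks (≥ 95 must recover every sign); the null calibration of the
whole synthetic-plus-ANOVA pipeline uses 200 reduced benchmarks with a
correspondingly widened binomial acceptance band.

## Known limitations

- The score's dependence on domain adjacency is inherent to the polygon
  construction; compare scores only under a fixed, recorded domain order.
- The mixed model treats a bounded proportion as Gaussian; a
  replicate-level logistic variant would respect the support but is not the
  default here (per-question accuracies at R = 3 take only 4 values, and the
  linear model is what the summary tables are built on).
- Holm and Tukey are the only multiplicity procedures; no Bayesian
  analyses.
- The Hedges-g CI is the large-sample normal approximation; it degrades for
  very small groups.
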