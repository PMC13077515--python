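# primellm

Grading, composite scoring and statistical comparison for multi-select
clinical-vignette benchmarks of large language models.

Stepwise clinical vignettes walk a model through the diagnostic workflow —
differential diagnosis (DD), diagnostic testing (DT), final diagnosis (FD),
management (M) and miscellaneous clinical reasoning (Q) — with
select-all-that-apply questions graded **all-or-nothing**: full credit only
when the selected option set equals the correct set exactly. Each vignette
is run in independent triplicate to capture model stochasticity.

Raw accuracy compresses this multidimensional performance into one pooled
number and hides uneven competence. The **PrIME-LLM score** (Proportional
Index of Medical Evaluation for LLMs) instead places the five per-domain
accuracies $r_1,\dots,r_k$ on the spokes of a radar chart and takes the area
of the resulting polygon, normalized by the area of the full-scale reference
polygon (a hypothetical model at 100% everywhere):

$$S \;=\; \frac{\tfrac12\sin(2\pi/k)\sum_{i=1}^{k} r_i\,r_{i+1}}{\tfrac12\sin(2\pi/k)\,k}
      \;=\; \frac{1}{k}\sum_{i=1}^{k} r_i\,r_{i+1} \qquad (r_{k+1}\equiv r_1).$$

$S\in[0,1]$, equals 1 only for a perfect profile, equals $a^2$ for a uniform
profile $(a,\dots,a)$, and penalizes unbalanced profiles: at a fixed mean,
spreading accuracy unevenly across adjacent domains strictly shrinks the
area. Because area depends on which domains are adjacent, the score is
invariant to rotations and reversals of the domain order but not to
arbitrary permutations; `order_sensitivity` reports the spread over all
cyclically distinct orderings.

The package provides:

- **`primellm.grading`** — strict set-equality grading, image-question
  exclusion for non-multimodal models, per-domain accuracy profiles
  (per-vignette two-stage or question-pooled), per-question raw accuracy,
  and failure rates (1 − accuracy) under arbitrary groupings.
- **`primellm.metric`** — polygon area, PrIME scores per replicate,
  per-model summaries (mean, SEM, min–max range), overall accuracy.
- **`primellm.stats`** — repeated-measures ANOVA with Holm-corrected paired
  t tests for question-level accuracy; between-subjects ANOVA with Tukey HSD
  for replicate-level PrIME scores; Welch/pooled two-sample contrasts with
  Cohen *d*, Hedges *g* (+ 95% CI), and the common-language effect size;
  Spearman correlation; linear mixed models with a random intercept per
  question; OLS at model level.
- **`primellm.synthetic`** — study-scale benchmark simulation from a
  logistic item-response model with known truth (21 models × 29 vignettes ×
  9 questions × 3 replicates by default), for end-to-end testing and
  parameter-recovery verification.
- **`primellm.io` / `primellm` CLI** — TSV/CSV tables, YAML run configs,
  SVG radar plots, and a full report bundle with a hashed manifest.

## Worked example

Simulate a small benchmark, grade it, and compare models:

```python
import primellm as p
from primellm.grading import domain_accuracy
from primellm.metric import prime_table

cfg = p.default_config(seed=1, n_models=5, n_vignettes=8)
keys, responses, truth = p.generate_benchmark(cfg)
graded = p.grade_benchmark(responses, keys, truth["multimodal_flags"])
scores, summary = prime_table(domain_accuracy(graded))
print(summary.round(3).to_string(index=False))
```

```
model_id  mean   sem   min   max  n_replicates
model_01 0.442 0.015 0.418 0.470             3
model_02 0.389 0.028 0.340 0.436             3
model_03 0.574 0.057 0.484 0.680             3
model_04 0.654 0.037 0.580 0.698             3
model_05 0.746 0.027 0.695 0.786             3
```

Each row is one model's PrIME score averaged over its three replicates with
the SEM and min–max range; the generator drew abilities increasing from
model_01 to model_05 and the score recovers that ordering. Replicate-level
scores support a between-subjects ANOVA:

```python
groups = [g["prime_score"].to_numpy() for _, g in scores.groupby("model_id")]
print(p.oneway_anova(groups).summary())
```

```
between-subjects one-way ANOVA: F(4, 10) = 17.05, p = 0.000183
```

i.e. with 5 models × 3 replicates the score separates models far beyond
chance. Planned contrasts come with effect sizes:

```python
tt, es = p.two_sample(reasoning_means, nonreasoning_means, variance_mode="welch")
# -> t, Welch df, p, Cohen d, Hedges g with CI, CLES
```

The same pipeline runs from the shell:

```bash
primellm simulate --seed 1 --outdir bench/
primellm grade --responses bench/responses.tsv --keys bench/keys.tsv --models bench/models.tsv
primellm score --graded graded.tsv --order DD,DT,FD,M,Q
primellm compare --scores prime_scores.tsv --groups bench/models.tsv
primellm report --seed 1 --outdir report/
```

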