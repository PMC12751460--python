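# nestmove

Bout-level movement analysis for isolated termite workers, linking **nesting
strategy** to **locomotion**. Termite species are either *one-piece nesters*
(the colony lives inside a single piece of wood that is both nest and food,
and never forages outside) or *foragers* (multiple-piece and separate
nesters that exploit food away from the nest). `nestmove` asks whether that
life-history difference is visible in how individual workers move in a
standardized circular arena — and provides everything needed to answer it
from tracked trajectories: segmentation of movement into pause/move bouts,
heavy-tailed bout-duration model fitting, wall-following quantification, and
hierarchical mixed-model contrasts. A synthetic trajectory generator with
the same statistical structure makes the whole pipeline testable without any
tracking data.

## What it computes

Given per-individual trajectories (x, y at 5 fps, mm-calibrated, 60 min in a
140 mm arena):

1. **Step lengths** between successive frames; steps > mean + 2 SD (per
   individual) are masked as tracking artefacts.
2. **Pause/move threshold** per species: the valley of the Gaussian kernel
   density of pooled step lengths, between the near-zero pause mode
   (< 0.5 mm) and the movement mode (> 0.5 mm). Steps ≥ threshold are
   *move*, others *pause*; runs of equal labels are **bouts**.
3. **Bout-duration models** fitted to pooled pause and move durations by
   discrete (bin-based) maximum likelihood on the 0.2 s frame grid:

   - stretched exponential `P(x) = λβx^{β−1} exp{−λ(x^β − x_min^β)}`
   - truncated power law `P(x) = (μ−1)x^{−μ} / (x_min^{1−μ} − x_max^{1−μ})`
   - exponential and pure power law as reference benchmarks,

   compared by AIC weights, with Kolmogorov–Smirnov D for absolute fit and
   inverse cumulative distributions (ICDFs) for tail comparison.
4. **Arena zones**: occupancy of the outer half of the arena (equal-area
   split at radius r/√2 — thigmotaxis), and **inner bouts** (runs ≥ 1.0 s
   inside the inner circle) scored by duration, path length, chord length
   and straightness index SI = chord/path.
5. **Contrasts**: every response compared between nesting types with a
   linear mixed model, `response ~ nesting_type + (1 | species/colony)`,
   REML, Type-II Wald χ² tests, variance decomposed into species / colony /
   residual percentages; proportions logit-transformed after adding 0.01
   (capped at 0.995).

## Worked example

```python
from nestmove import StudyConfig, default_cohort_spec, run_pipeline

result = run_pipeline(StudyConfig(cohort=default_cohort_spec()), seed=1)
print(result.report)
```

prints (abridged):

```
Individuals analysed: 125 across 5 species.
Mean standardized distance, forager: 4711.1 body lengths
Mean standardized distance, one_piece: 597.9 body lengths

Per-species pause/move thresholds (mm): forager_a=0.606, forager_b=0.661,
forager_c=0.688, one_piece_a=0.249, one_piece_b=0.277

Best-supported duration model per species x behaviour:
  forager_a/move: stretched_exponential (w=1.000, D=0.008, n=4798)
  ...
Nesting-type contrasts (forager - one_piece):
  distance_bodylengths: estimate=4.11e+03, chi2=8.19, p=0.00421,
    variance% (species/colony/residual)=87.5/7.8/4.7
  prop_outer: estimate=2.88, chi2=30.60, p=3.16e-08, ...
  mean_bout_duration_s: estimate=-52.4, chi2=8.72, p=0.00314, ...
  mean_bout_straightness: estimate=0.446, chi2=21.75, p=3.1e-06, ...
```

Reading this: the 75 synthetic forager workers traveled ~8× farther (in body
lengths) than the 50 one-piece workers; each species' step-length density
gave a clean pause/move valley; the stretched exponential out-weighed the
truncated power law for every species and behaviour (bout durations are
constrained, not scale-free); and under the nested mixed model foragers
traveled significantly farther (χ²₁ = 8.19, p = 0.004), occupied the outer
region more, and crossed the inner region in shorter, straighter bouts. The same `result` object carries the per-individual study table,
the fitted duration models and the zone metrics. The `examples/` scripts
walk through each capability separately; real tracking exports can be
analysed by pointing `StudyConfig` at a directory of `frame,x,y` CSVs plus a
metadata table, or through the `nestmove` command-line interface
(`convert`, `segment`, `fit`, `zones`, `run`).

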