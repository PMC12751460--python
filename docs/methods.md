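# Methods

`nestmove` implements a bout-level analysis of individual termite-worker
locomotion in a circular open-field arena, together with a synthetic
trajectory generator that reproduces the statistical structure the analysis
assumes. This note records the models, the numerical choices, and what the
synthetic tests do and do not demonstrate.

## The analysis pipeline

**Step lengths and artefact removal.** The unit observation is the step
length: the Euclidean displacement of the tracked body centre between
successive frames at the 5 fps analysis rate (frame interval 0.2 s), in mm.
Steps larger than mean + 2 SD, with both moments computed per individual on
the raw series, are masked as tracking artefacts (animals climbing the arena
wall and tumbling back produce large spurious displacements). Masked values
are retained for audit but excluded from all pooled densities, sums and bout
labels. Masking precedes threshold estimation so that artefacts cannot
distort the kernel density; this ordering is an interpretation, exposed as a
configuration switch, as is the choice to sum traveled distance over the
cleaned rather than the raw series.

**Pause/move threshold.** Valid steps are pooled across all individuals of a
species and a Gaussian kernel density with Silverman's bandwidth is
evaluated on a fixed grid of 2,001 points from 0 to the maximum step. The
pause mode is the density maximum below 0.5 mm; the movement mode is the
largest local maximum above 0.5 mm; the threshold is the density minimum
(valley) strictly between them. The valley must be strictly lower than both
modes, otherwise the input is rejected as unimodal — the threshold is never
silently defaulted. Samples larger than 50,000 steps are first binned into
4,096 weighted points; the bandwidth is still computed from the raw sample,
so the evaluated density is the same to within the bin width while the cost
stays independent of sample size. One threshold per species is used
(per-individual thresholds are out of scope).

**Bouts.** Steps below the threshold are labelled pause; steps at or above
it, move. Maximal runs of identically labelled valid steps become bouts with
duration = run length x 0.2 s. Runs are split, never bridged, across masked
steps: an artefactual displacement gives no evidence that the behavioural
state continued. Per individual the pipeline reports total traveled distance
(also standardized by body length), the pause proportion (pause frames over
labelled frames), and moving speed (mean of steps at or above the threshold,
divided by the frame interval to give mm/s; an explicit missing value when
no step crosses the threshold).

**Duration models.** Four families are fitted to the pooled pause and move
durations of each species, written with x >= x_min throughout:

- stretched exponential: P(x) = lam beta x^(beta-1) exp{-lam(x^beta - x_min^beta)},
  lam > 0, 0 < beta <= 1 — strongly constrained movement, long bouts decay fast;
- truncated power law: P(x) = (mu-1) x^(-mu) / (x_min^(1-mu) - x_max^(1-mu)),
  mu > 1 — scale-free movement with a physical cut-off;
- exponential and pure power law as reference benchmarks (the beta = 1
  boundary and the x_max -> infinity limit of the two main families).

Because durations are recorded on a 0.2 s grid, fitting uses discrete
CDF-based likelihoods: a recorded duration d occupies the bin [d, d + grid),
contributing log[F(d + grid) - F(d)], with the final bin of the truncated
family closed at x_max. x_min is fixed at one grid step (bouts of a single
frame are observed; there is no x_min selection scan) and x_max for the
truncated power law is fixed at the upper edge of the last occupied bin
(max observed duration + grid) — taking the maximum observed value itself
would give the observed maximum a zero-width, zero-probability bin. Free
parameter counts follow from this: 2 for the stretched exponential, 1 for
each other family. Optimization is a bounded quasi-Newton (L-BFGS-B) search
restarted from a deterministic coarse grid (5 x 5 for the stretched
exponential, whose likelihood can be flat along a (lam, beta) ridge), so
fits are exactly reproducible. Non-convergence, parameters stuck at search
bounds and degenerate (single-valued) inputs are flagged on the result,
never silently ignored. Support is compared by AIC weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2); absolute fit is reported as
the Kolmogorov-Smirnov D between the empirical CDF and the discrete model
CDF on the grid. Inverse cumulative distribution functions (proportion of
bouts with duration >= x) are provided for log-log tail comparison.

Two structural notes on model selection with this k-counting convention.
Truncating at the observed maximum strictly increases the likelihood on any
data set, so the truncated power law dominates the pure power law (equal k)
by construction — the pure power law can never win an AIC comparison here.
Similarly, on exponential data the stretched family attains at least the
exponential likelihood at the beta = 1 boundary and gains a half-chi-square
improvement with probability 1/2, so it out-weighs the exponential in ~8% of
replicates no matter the sample size. Selection-consistency checks are
therefore meaningful exactly for the two main, non-nested families.

**Arena zones and inner bouts.** The arena floor (radius 70 mm) is split
into equal-area halves by the concentric circle of radius 70/sqrt(2) mm.
Occupancy of the outer annulus measures wall-following (thigmotaxis).
Inner bouts are maximal runs of frames strictly inside the inner circle
lasting at least 1.0 s (5 frames); frames exactly on the boundary count as
outer (arbitrary but fixed, measure-zero for real data). Entry and exit
points are the first and last frames inside (no boundary interpolation).
Each bout is scored by duration, path length (sum of raw within-bout
steps), chord length between entry and exit, and straightness index
SI = chord/path; bouts containing a masked step are discarded because the
artefact invalidates the crossing geometry, and SI is missing when the path
length is zero. Bout metrics are averaged per individual; individuals that
never entered the inner region are flagged and excluded from those averages.

**Contrasts.** Every per-individual response is compared between one-piece
nesters and foragers with a linear mixed model: nesting type as the single
fixed effect and colony nested within species as random intercepts
(1 | species/colony), fitted by REML (statsmodels MixedLM with a
variance-component formula for the colony level). Significance is a Type-II
Wald chi-square test, which for a single-term model is (estimate/SE)^2 on
1 df. Proportions (pause proportion, outer occupancy) are transformed by
logit(min(p + 0.01, 0.995)): the +0.01 keeps observed zeros finite, and the
0.995 cap extends the same protection to proportions at exactly 1 (outer
occupancy of wall-followers is often 1.0), preserving monotonicity. The
response is standardized internally before fitting and the estimates are
scaled back, which makes the Wald statistic numerically invariant under
affine rescaling of the response. Random-effect variances (species, colony,
residual) are reported as percentages of their total; this component/total
convention is one of several possible decompositions for a model whose
fixed effect also separates species. Singular fits (a variance component on
the zero boundary, or convergence warnings) are flagged, not suppressed; no
multiple-testing correction is applied (each response is tested once).
Within-species Pearson correlations between body length and traveled
distance check that body size does not drive the distance contrast.

## The synthetic generator

The walker is a renewal process: alternating pause and move bouts with
durations drawn by inverse-CDF sampling from the same duration families the
fitting stage estimates. Continuous draws are discretized by flooring to the
frame grid (minimum one frame), which is exactly the bin convention of the
discrete likelihood — a recorded duration d stands for a true duration in
[d, d + grid) — so parameter recovery is unbiased by construction. While
moving, the heading is a correlated random walk (Gaussian turning noise per
frame) and the per-frame displacement is Gaussian around speed_mean/fps,
truncated at +-2 SD: stride lengths are physiologically bounded, and the
truncation guarantees that in artefact-free synthetic data the per-individual
mean + 2 SD filter — whose cutoff is inflated by the pause/move bimodality
itself — never masks legitimate locomotion. While pausing, displacements are
half-normal jitters (scale 0.03 mm) in random directions. Within a zone of
width `wall_zone` from the wall, the heading is pulled toward the nearer
wall-tangent orientation with weight `wall_bias` in [0, 1] (soft
thigmotaxis); any frame landing outside the arena is projected back onto the
boundary. This soft-bias-plus-projection scheme produces sustained
wall-following without asserting collision physics no one measured.

Cohorts mirror the study design: five species (two one-piece nesters, three
foragers), five colonies per species, five workers per colony, 60-min
recordings at 5 fps in a 140 mm arena. Colony random intercepts multiply
speed on the log scale (SD 0.1) — a single, controllable between-colony
channel, consistent with colony explaining only a few percent of variance in
the study system. Because no species-level movement parameters exist to
copy, the archetypes are free design choices that encode the qualitative
contrasts the analysis should recover, and nothing else:

| | one-piece (a, b) | foragers (a, b, c) |
|---|---|---|
| move-bout model (SE lam, beta) | (1.1, 0.90), (0.9, 0.85) | (0.30, 0.55), (0.40, 0.60), (0.55, 0.65) |
| pause-bout model | SE(0.8, 0.8) shared by all species | same |
| speed mean (mm/s) | 3, 4 | 7, 9, 11 |
| speed SD | 12% of mean | 12% of mean |
| turning noise (rad/frame) | 0.45, 0.40 | 0.18, 0.15, 0.20 |
| wall zone (mm) / bias | 8 / 0.45, 8 / 0.50 | 12 / 0.85-0.90 |
| body length (mm) | 9.0, 11.0 | 9.5, 5.0, 4.0 |

Foragers thus travel farther, persist in movement once started (heavier
move-bout tails; a few percent of move bouts exceed 100 s), hug the wall
more, and cross the centre fast and straight; one-piece nesters make short
move bouts, pause more, and wander the centre slowly and tortuously.

What the generator does **not** emulate: tracking artefacts (so the outlier
filter is exercised only by constructed fixtures), wall climbing and 3-D
posture, interactions between animals, within-bout speed autocorrelation,
and any calibration to the real deposited trajectories. Passing synthetic
tests therefore demonstrates correctness of the estimators and the expected
qualitative ordering under the assumed generative structure — not that real
termites satisfy those assumptions.

## Calibration of the Wald test

The type-I error and power of the nesting-type contrast are checked on
directly simulated Gaussian response tables (species, colony and residual
effects with variance shares 57.5% / 3.8% / 38.7%, matching the study
system's traveled-distance decomposition). The simulation design uses 15
species per nesting type (3 colonies x 4 workers each): the species-level
contrast then has enough denominator degrees of freedom for the nominal
chi-square reference to be meaningful. With the real study's 2-vs-3 species
layout the same Wald test is intrinsically anticonservative (the contrast
has ~3 effective df, so the true size at nominal 0.05 is roughly 0.12-0.15
regardless of implementation) — a known limitation of few-level random
effects that applies to the original design as much as to this
re-implementation. Power is assessed against a +3 species-SD shift applied
to the forager species means.

## Problem sizes and determinism

Default test and acceptance problem sizes: n = 10,000 bouts for parameter
recovery, 100 seeded replicates of n = 5,000 for model selection, n = 20,000
steps for threshold recovery, 200 + 200 simulations for Wald calibration,
and 50 seeded end-to-end runs of the full 125-worker cohort for directional
recovery. Every stochastic step is driven by an explicit seed; identical
seeds give byte-identical tables. The per-frame walker loop is compiled with
numba (the wall-bias coupling between position and heading makes the
recursion inherently sequential), so a full cohort simulates in about a
second.

## Known limitations

- One threshold per species; individuals far from their species' kinematic
  norm are segmented with a borrowed threshold.
- The discrete likelihood treats pooled bouts as independent, ignoring
  within-individual autocorrelation; AIC weights inherit that assumption.
- The truncated power law's x_max is data-dependent (fixed at the last
  occupied bin edge), which makes its AIC comparison against the pure power
  law structurally one-sided (see above).
- Variance percentages condition on the fitted fixed effect; other
  decompositions (marginal/conditional) would give different shares.
- The logit cap at 0.995 is a pragmatic symmetric guard; responses that
  saturate at 1.0 compress near the cap.
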