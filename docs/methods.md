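# Methods

## Detection model

A detected spot is a surface-captured complex carrying `m` copies of the
tagged protein. Each copy is fluorescent independently with probability `p`
(reporter activity), so the number of fluorescent copies — and hence the
number of photobleaching steps — is `Binomial(m, p)`. Spots with zero
fluorescent copies are never detected, so the observable counts follow the
zero-truncated binomial

    P(X = x | m, p) = C(m, x) p^x (1−p)^(m−x) / (1 − (1−p)^m),  1 ≤ x ≤ m.

A population with `g` sub-populations (copy numbers `m_1 < … < m_g`,
proportions `π_1 … π_g`) yields a finite mixture of these distributions.
Detection is assumed independent within and between complexes, and `p` is
treated as known from a dual-tag calibration (defaults: mNG 0.74,
SNAPf 0.78). One analysis in the literature applies 0.78 for mNG; activity
is therefore a per-fluorophore configuration value rather than a constant.

The pmf is evaluated in log space with log-gamma binomial coefficients and
is stable for `m` well beyond 100.

## Maximum likelihood estimation

EM over all parameters fails here because the component sizes determine the
support of the likelihood. The fit instead alternates two exact stages:

- **Sizes at fixed weights** — exhaustive search over all `g`-subsets of the
  admissible size grid (`1..m_max`, optionally restricted, e.g. to even
  sizes for obligate dimers). Subsets whose largest size is below the
  largest observed count are infeasible and skipped; if no subset is
  feasible the fit raises with instructions to raise `m_max`.
- **Weights at fixed sizes** — EM responsibility updates, closed-form and
  provably non-decreasing in the likelihood. The weight subproblem is
  concave (log of a linear function of the weights), so EM converges to its
  global optimum.

The stages repeat until the relative log-likelihood change falls below
`tol` (default 1e-8), with the best of `n_starts` restarts kept (first start
uniform weights, the rest Dirichlet(1)). Because the alternation can have
disconnected basins in the size variables, a refinement pass then runs the
weight-EM from a uniform start on the top-ranked candidate subsets (all of
them when at most 2,000 are admissible); since each per-subset weight
problem is solved globally, the returned fit is the exact global maximum
whenever the sweep is exhaustive — which covers every configuration used in
the tests, and is verified against a brute-force enumeration oracle.
The recorded log-likelihood trace is non-decreasing on every run and is
asserted in the test suite. Components whose fitted weight falls below 1e-6
are pruned (degenerate-solution guard) and the remaining weights refitted.

Defaults: `m_max = 20` (about twice the largest copy numbers reported in
practice), `k_max = 6`, `n_starts = 10`, `max_iter = 500`.

## Model selection

The number of sub-populations is chosen as `argmin_k AIC(k)` over
`k = 1..k_max`, ties broken toward fewer components. Two AIC variants are
provided: the default `"paper"` form `2(2k−1) − log L`, and the canonical
`"standard"` form `2(2k−1) − 2 log L`. The default penalizes the negative
log-likelihood once rather than twice; both are exposed because the two
conventions coexist in published analyses and differ only in how strongly
extra components must pay for themselves (the default is the stricter of
the two). Replicates are pooled before fitting by default; per-replicate
fitting is available by calling the fit on each replicate's counts.

## Corrected stoichiometry distribution

The fitted weights `π̂_j` are sub-population proportions *among detected
spots*. A complex of size `m` is detected with probability `1 − (1−p)^m`,
so detected spots over-represent high-copy sub-populations. The corrected
(population) distribution divides each weight by its component's detection
probability and renormalizes:

    π_j^pop ∝ π̂_j / (1 − (1−p)^(m̂_j)).

For a single component this is a no-op on the weights (the result is all
mass at `m̂_1`); for mixtures it removes a bias that is analytically
`≈ 5%` for a 60/40 monomer/dimer population at `p = 0.74` and grows with
the spread of component sizes. The model-implied observed-step distribution
(the fitted mixture pmf) is returned alongside for overlay on the raw
histogram.

## Two-sample testing

Step-count distributions between conditions are compared with the
two-sample Kolmogorov–Smirnov statistic, `sup_x |F̂_a(x) − F̂_b(x)|` over
the integer support. Counts are discrete, so p-values come from a pooled
nonparametric bootstrap: both groups are resampled with replacement from the
pooled sample at their original sizes (implemented as multinomial draws over
the pooled support, which is distributionally identical and vectorizes), and

    p = (1 + #{D* ≥ D_obs}) / (n_boot + 1),

an estimator that cannot return zero and is exactly invariant to swapping
the two samples. Type-I calibration at the nominal 5% level is verified by
simulation in the test suite. The bootstrap resamples raw counts, not
replicate-level percentages, because the statistic is defined on samples.

## Preprocessing and background subtraction

Spots with zero counted steps are removed and tallied. Background (dust,
non-specific binding) is estimated from a non-tagged control sample and
subtracted per step after multiplying by an explicit scale factor that
converts the control counting effort (fields imaged × dilution) to the
experimental one; the factor defaults to 1 and is always recorded, because
a silently mismatched effort is the dominant failure mode of this step.
Negative corrected counts are clipped at zero with a logged warning, and
percentages are renormalized to 100 after any subtraction. Replicate
summaries report per-step mean and sample SD of percentages, with steps
absent from a replicate counted as 0%.

## Co-localization

Channel registration is a least-squares affine map estimated from at least
three non-collinear fiducial bead pairs, reported with its RMS residual.
Spot matching applies the map to the second channel and pairs each reference
spot with its nearest mapped partner within 3 px (configurable). By default
matching is one-to-one (greedy nearest-first, ties toward the smaller spot
id) to avoid double counting; the literal per-spot nearest-neighbor variant,
which permits many-to-one pairs, is available via a flag. Mapped coordinates
are used for the distance rule.

Raw co-localization frequency is matches over reference spots; the
false-positive rate measured in a no-tag control field is subtracted and
the result clipped at zero. When the partner protein is present as a single
copy, its true occupancy is the observed frequency divided by the reporter
activity (capped at 1), because a single-copy partner is visible only when
its one reporter is active. Without knowledge of the partner's stoichiometry
distribution no such correction is possible and the uncorrected frequency is
a lower bound.

Intensity-based single/multicopy classification uses a manual cutoff, or an
automatic proposal at the KDE valley between the first two modes (always
reported for override; unimodal distributions raise and demand a manual
value). Association between paired log-intensities is tested by Spearman
correlation with a seeded permutation p-value — a deliberate simplification
of smoother-based regression, sufficient for the monotone-association
question.

## Synthetic data

The generator emulates what the analysis consumes, not the raw images: no
point-spread function, camera noise, or spot detection. Counts are drawn
exactly under the detection model (mixture draw → binomial thinning → zero
truncation with discards tallied); background contaminants are injected at a
configurable expected share of retained spots, defaulting to one-step counts
(control and RNase-resistant spots show mostly single-step bleaching);
control samples contain background only. Two-color fields place complexes
uniformly at random, detect each channel independently, shift channel B by
a configurable registration offset, and model spot intensity as linear in
the active-molecule count with additive Gaussian noise — the simplest model
consistent with the observed intensity–step-count correlation. Traces are
piecewise constant with independent geometric per-molecule bleach times
(hazard `bleach_rate` per frame) plus Gaussian noise; the movie length must
satisfy P(all molecules bleach) > 0.99.

Passing tests on these data validate the estimation machinery under the
model's own assumptions. They do not probe real-data complications such as
blinking, partial bleaching steps, drift, variable step heights, or spatially
structured background.

All randomness flows from a single seed; independent streams are derived
with `SeedSequence.spawn`, so adding a stream never perturbs the others, and
every artifact records its seeds and configuration hash. Reruns of the
pipeline are byte-identical.

## Step counting on traces

The bundled step counter is greedy binary segmentation with an L2 cost and
a per-change-point penalty, defaulting to `2σ̂² log n` with `σ̂` estimated
from the median absolute successive difference (robust to the steps
themselves). Only downward mean changes count (photobleaching only; blinking
is not modeled). When the single-fluorophore step height is known, segment
means are snapped to integer levels, which both suppresses sub-threshold
spurious splits and resolves simultaneous double-bleach events into their
true multiplicity; exact-recovery accuracy at noise SD 0.2× the step height
exceeds 99% in simulation (the test suite asserts ≥ 95% on 200 traces).
It is a deliberately plain detector for exercising synthetic traces, not a
re-implementation of production change-point software.

## Problem sizes

The test suite and demo pipeline run at sizes chosen to make the statistical
assertions sharp while staying desk-scale: mixture recovery at n = 2,000 to
5,000 counts, goodness-of-fit at n = 50,000, KS type-I calibration with 500
repeats of n = 500 per group at 2,000 bootstrap replicates, and the
end-to-end trace pipeline at n = 10,000 spots with 400-frame movies
(bleach hazard 0.02/frame, noise SD 0.2× step height), where the recovered
stoichiometry distribution lands within total-variation distance 0.05 of
the generative truth.

## Known limitations

- Reporter activity `p` is treated as known; its calibration uncertainty
  (± 6–7 percentage points) is not propagated into the fit.
- No uncertainty quantification on `m̂` or `π̂` (no bootstrap CIs on the
  corrected distribution).
- The AIC selection inherits the usual finite-mixture caveats; the
  number of sub-populations *sampled* may be smaller than the number in the
  population, and nothing estimates the latter.
- Per-spot posterior sub-population assignments are not exposed.
- The two-stage parametric test sketched by the alternating-fit framework
  (first compare `g`, then the parameters) has no off-the-shelf calibration
  and is intentionally not implemented; the bootstrap KS test is the
  supported comparison.
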