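# Methods

`retestkit` quantifies the natural variability of precise, repeated
behavioural assessments — the setting where a robotic or computerized test
battery yields dozens of continuous parameters per participant and the
question is whether a change between two assessments reflects a real
change in ability or just measurement noise. All statistics operate on
standardized (Z-score) parameter values from a cohort assessed twice.

## The measurement model

For participant *i*, parameter *p* and session *j* ∈ {1, 2}, the observed
Z-score is modelled as

    x_ijp = s_ip + L_p·1[j = 2] + e_ijp

with subject ability `s_ip ~ N(0, σ_s²)` shared by both sessions, session
measurement error `e_ijp ~ N(0, σ_e²)` independent across sessions, and a
fixed learning (practice) shift `L_p` at the second session. Parameters
that are averages over trials add within-session trial noise
`τ ~ N(0, σ_trial²)` around the session value. Everything the package
computes has a closed form under this model, which is what the test suite
exploits:

| quantity | definition | model expectation |
|---|---|---|
| SD_diff | SD of session-2 − session-1 differences | √2·σ_e |
| CI | 1.64 · SD_diff | 1.64·√2·σ_e |
| SC | √2 · CI | 2·1.64·σ_e |
| ICC-C | (MS_S − MS_E)/(MS_S + MS_E) | σ_s²/(σ_s² + σ_e²) |
| learning effect | mean difference | L_p |
| pooled SEM | RMS of per-series SEMs | σ_trial/√n_trials |
| IS error | pooled SEM · √2 · 1.64 | — |

The 1.64 multiplier is the one-tailed 95% convention: the usual clinical
question is directional (has this person improved, or deteriorated?). For
the non-directional question a 1.96 multiplier is more appropriate; the
multiplier is a `ThresholdConfig` field rather than a constant.

## Normalization and one-sided transforms

Raw parameter values are mapped to Z-scores by an iterative loop: shift
to positivity (once, by `1 − min` if any value is ≤ 0), Box-Cox de-skew
with the maximum-likelihood λ (bounded to [−5, 5], found by bounded
scalar minimization of the negative Box-Cox log-likelihood), standardize,
and trim observations with |Z| > 3.29 (~0.1% two-sided normal mass);
repeat until nothing is trimmed or 10 iterations. Ten iterations is a
safety cap — on realistic data the loop converges in 2–3 passes. Applying
a fitted model to new values below the training positivity range floors
them just above zero; they map to extreme negative Z-scores rather than
erroring.

Refitting the model on its own standardized output is *approximately*
idempotent, not exactly: the second fit's λ̂ differs from 1 by a
finite-sample O(n^−1/2) wobble, which perturbs the re-transformed values
slightly. The test suite therefore asserts the meaningful form of
idempotency — the refit trims essentially nothing and the composed
transform stays close to the identity — rather than exact parameter
equality.

One-sided parameters (where one direction is always worse) are folded by

    zeta(z) = √2 · erfcinv(0.5 · erfc(z/√2))  =  Φ⁻¹((1 + Φ(z))/2),

the standard-normal quantile of the folded CDF: zeta(0) = 0.6745 (the
75th percentile), zeta(z) → z as z → +∞, and the codomain is (0, ∞). At
double precision the fold saturates at exactly 0 for z below about −8
(the folded tail mass falls under the resolution of 1.0); this is far
outside any realistic score. Parameter scores for a task are combined by
the root-sum-square (Euclidean) distance — missing components are dropped
from the sum, not imputed — or alternatively by Mahalanobis distance with
a covariance estimated from the reference cohort plus a ridge of
1e−8·trace(Σ)/dim for invertibility. The distance is re-standardized
against the reference cohort's distances (the Z-Task Score) and folded
once more into the one-sided Task Score.

A symmetric interval z ± CI on the two-sided scale becomes asymmetric
after the fold: `task_score_ci` maps the endpoints through the same
transform. The upper distance exceeds the lower near z = 0 (0.735 vs
0.474 for CI = 1) and both approach CI from below as z grows — so the
better the performance, the smaller the change that counts as
significant on the one-sided scale. A published variant of the bound
formula inserts the CI as "0.5 + 0.5·erfc(...)", which would confine
outputs to (−0.674, 0.674) and contradict both the transform's codomain
and the ~68.3% coverage of Task Score 1; we read it as a typographical
slip and apply the standard one-sided form to the shifted endpoints.

## Reliability thresholds and ICC

Paired differences with |d| > 3.2 (a magnitude expected ~1/1000 times
under independence) are flagged as outliers and excluded from SD_diff,
ICC and learning tests alike; the boundary is strict (exactly 3.2 is
retained) and flagged counts are reported, never silently dropped.
SD_diff uses the n−1 denominator.

The consistency ICC comes from a two-way crossed (subjects × sessions)
decomposition: MS_S is the between-subject mean square, MS_E the residual
after removing subject *and* session main effects, so a constant
session-2 shift — a learning effect, which is modelled separately — does
not depress the ICC. The default formula is the two-session consistency
form (MS_S − MS_E)/(MS_S + MS_E), whose expectation is the variance ratio
σ_s²/(σ_s² + σ_e²) and which is 0 when subjects are indistinguishable.
The simpler ratio MS_S/(MS_S + MS_E) appears in some write-ups of this
framework; it tends to 0.5, not 0, under no subject effect, so it is kept
only behind the `literal_eq5` flag for fidelity comparisons. Agreement
ICC (which folds systematic shifts into error) is deliberately out of
scope. When only a single-session SD is available,
`sd_diff_from_icc` applies the standard substitution
SD_diff = SD_pre·√(1 − ICC).

## Learning effects and multiplicity

Each parameter gets a two-sided paired t-test on the outlier-excluded
differences. Degenerate inputs are resolved explicitly: all differences
zero → p = 1; identical nonzero differences → infinite t, smallest
positive p. With >150 parameters in a typical battery, Bonferroni is too
conservative; p-values are corrected by the Benjamini–Hochberg step-up
procedure over the whole run as one family (a per-task family option
exists). The implementation delegates to statsmodels' `fdr_bh`; the test
suite checks it against an exhaustive brute-force oracle that tries every
rejection threshold.

## Probabilistic classification

`classify_impairment` treats the latent true score as Normal around the
observation with SD = CI/1.64, which makes the probability of true
impairment exactly 0.5 at the threshold and exactly the 1.64-quantile
tail masses (≈5%/95%) at threshold ∓ CI. Note Φ(1.64) = 0.9495, so "5%"
is the convention's nominal value, exact only at the corresponding
quantile 1.6449. Boundary ties go to the more severe category on the
impairment side (≥ threshold + CI is impaired); for change classification
the strict inequalities |Δ| > SC define improvement/worsening and an
exact tie remains `possibly_changed`.

## Simulations

The sample-size study draws n standard-normal values per replicate
(10,000 replicates per grid point, default grid 5..100, each grid point
on an independent child stream spawned from the master seed) and reports
the variance of the sample mean and sample SD — analytically 1/n and
≈1/(2n). Both stabilize around n = 50 (var(mean) ≈ 0.02, var(SD) ≈ 0.01),
the basis for the ~50-participant minimum cohort. The Task-Score CI study
draws 10,000 standard-normal Z-Task Scores and pushes them, ±CI, through
the one-sided transform.

## What the generator does and does not emulate

Defaults mirror the study conditions the framework targets: 56
participants per task, learning shifts of a few tenths of a Z-unit,
20–25 trials per session for trial-based tasks, and session error well
below between-subject spread. Outliers are injected at session level with
random sign (the outlier rules operate on session and difference scores),
the learning shift is a fixed effect (it is estimated as a mean
difference), and trial noise is independent of session error (SEM and
SD_diff are treated as separate quantities). The generator produces
already-normalized Gaussian Z-scores: it does not emulate raw kinematics,
skewed pre-normalization distributions, age/sex covariate structure, or
within-session learning curves. Passing tests therefore validate the
statistical machinery under the model's assumptions — they do not certify
behaviour on un-normalizable or covariate-confounded real data.

## Problem sizes and numerical choices

Test and simulation sizes are chosen so every closed-form target is
separated from its Monte Carlo noise by ≥3 standard errors while the full
suite stays fast: n = 2,000 cohorts for moment recovery, n = 5,000 for
ICC convergence, 10,000 replicates for calibration rates, 10,000-point
normalization fits. All randomness flows through
`numpy.random.default_rng` with explicit seeds; grid-point streams are
spawned via `SeedSequence` so results are independent of evaluation
order. CSV output uses `%.17g` and reading uses round-trip float parsing
so write→read cycles are bit-exact.

## Known limitations

Two sessions only (the design the thresholds are defined for); no
absolute-agreement ICC or bootstrap ICC intervals; no nonparametric
(Wilcoxon) alternative for non-normal differences; no modelling of
trial-order effects within a session; the reference-cohort normalization
here is a single-sample standardization, not a demographic regression
(age, sex, handedness) against a large normative database.
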