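# retestkit

Test–retest variability analysis for repeated behavioural assessments.

Precise assessment tools — robotic test batteries, computerized cognitive
tasks — measure performance finely enough that the hard question is no
longer *what is the score* but *has it really changed*. `retestkit`
answers that for cohorts assessed twice: it computes, per parameter and
per composite task score,

* **SD_diff** — the SD of session-2 − session-1 differences (after
  excluding |Δ| > 3.2 outliers),
* **CI = 1.64·SD_diff** — the band containing ~90% of healthy retest
  differences (one-tailed 95% each way),
* **SC = √2·CI** — the threshold an observed change must exceed to be a
  statistically real change,
* **ICC-C** — consistency intraclass correlation
  (MS_S − MS_E)/(MS_S + MS_E), the share of variance due to stable
  between-participant differences,
* **learning effects** — mean session-2 − session-1 shifts, tested with
  paired t-tests and Benjamini–Hochberg FDR correction across the whole
  parameter family,
* **IS error** — the within-session trial-sampling contribution,
  pooled SEM·√2·1.64, directly comparable to SC,

plus the score transforms the framework rests on: iterative
Box-Cox-and-trim normalization to Z-scores, the one-sided fold
ζ(z) = √2·erfcinv(½·erfc(z/√2)) = Φ⁻¹((1+Φ(z))/2), RSS/Mahalanobis
composite distances, one-sided Task Scores with asymmetric confidence
bounds, and probabilistic impairment/change classification. A synthetic
paired-assessment generator with known ground truth
(x = subject ability + learning shift + session error, trials = session
value + trial noise) drives the tests and examples. See
`docs/methods.md` for the model and the design choices.

## Worked example

```python
import retestkit as rk

ci = 0.95                      # measured CI of a reaction-time parameter
print(round(rk.sc_from_ci(ci), 2))          # 1.34  <- significant change
call = rk.classify_impairment(2.2, threshold=1.64, ci=ci)
print(call.category, round(call.probability_impaired, 3))
# possibly_impaired 0.833
r = rk.task_score_ci(0.0, ci=1.0)
print(round(r.task_score, 4),
      round(r.upper_bound - r.task_score, 3),
      round(r.task_score - r.lower_bound, 3))
# 0.6745 0.735 0.474
```

With a measured retest CI of 0.95 Z-units, a score must move by more
than 1.34 before the change outruns natural variability; an observed
score of 2.2 is above the 1.64 impairment cutoff but true impairment is
only ~83% probable, so it falls in the "possibly impaired" band
(0.69–2.59). The last lines show the one-sided Task-Score fold: a ±1
interval on the two-sided scale becomes +0.735/−0.474 after folding.

For complete end-to-end runs see `examples/`:
`simulate_and_analyze.py` (synthetic cohort → full report table),
`task_score_confidence.py`, `impairment_and_change.py`,
`sample_size_study.py`, and `published_summary_check.py` (the bundled
published per-task summary and its arithmetic). A thin CLI wraps the
same library calls:

```bash
retestkit simulate --n-participants 56 --out synth/
retestkit analyze synth/assessments.csv --out report/
retestkit sample-size --out curve.csv
retestkit classify --observed 1.64 --ci 0.95
```

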