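"""Probabilistic impairment and change calls for a reaction-time score.

Uses the measured reaction-time confidence interval of 0.95 Z-units with
the conventional impairment threshold of 1.64 (worse than ~95% of healthy
controls).  The score axis splits at 1.64 - 0.95 = 0.69 and
1.64 + 0.95 = 2.59; between them, impairment is uncertain.
"""

import retestkit as rk

CI = 0.95
SC = rk.sc_from_ci(CI)
print(f"CI = {CI}  ->  significant change SC = sqrt(2) x CI = {SC:.2f}")
print()

for observed in (0.3, 0.69, 1.64, 2.2, 2.59, 3.5):
    call = rk.classify_impairment(observed, threshold=1.64, ci=CI)
    print(
        f"score {observed:5.2f}: {call.category:18s} "
        f"P(truly impaired) = {call.probability_impaired:.3f}"
    )
print()

for first, second in ((1.0, -0.6), (1.0, 1.5), (1.0, 2.6)):
    call = rk.classify_change(first, second, sc=SC)
    print(f"assessment 1 = {first}, assessment 2 = {second}: {call.category}")
print()
print(
    "A score of exactly 1.64 is a coin flip (P = 0.5); only beyond 2.59 "
    "is true impairment more than ~95% likely.  Between two assessments, "
    "a drop larger than SC = 1.34 counts as statistically real improvement."
)
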