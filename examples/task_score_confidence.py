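"""One-sided Task-Score transform and its asymmetric confidence interval.

The two-sided Z-Task Score is folded onto a one-sided 0-to-infinity scale
(0 = best).  A symmetric interval z +/- 1 on the two-sided scale becomes
asymmetric after the fold: near z = 0 the upper distance is ~0.74 but the
lower only ~0.47, and both approach 1 for strongly impaired scores.
"""

import retestkit as rk

print("zeta(0)    =", round(rk.zeta_transform(0.0), 4), " (75th pct of the normal)")
print("zeta(1.64) =", round(rk.zeta_transform(1.64), 4))
print()

print("  z    task_score   point-lower   upper-point")
for z in (-2.0, -1.0, 0.0, 1.0, 2.0, 4.0):
    r = rk.task_score_ci(z, ci=1.0)
    print(
        f"{z:5.1f}   {r.task_score:9.4f}   {r.task_score - r.lower_bound:10.4f}"
        f"   {r.upper_bound - r.task_score:10.4f}"
    )

sim = rk.task_score_ci_simulation(n=10_000, ci=1.0, seed=0)
print()
print(
    f"fraction of 10,000 standard-normal scores with Task Score <= 1: "
    f"{100 * sim.fraction_at_most(1.0):.1f}%"
)
print(
    "That ~68.3% mirrors the +/-1 mass of the standard normal: the fold "
    "maps (-1, 1) onto (0, 1).  Both CI distances stay below 1 and grow "
    "toward 1 as the score worsens, so better performers need a smaller "
    "change for it to be significant on the one-sided scale."
)
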