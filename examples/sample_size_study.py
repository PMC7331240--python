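"""Monte Carlo stability of the sample mean and SD versus cohort size.

For each candidate n, draws n standard-normal values 10,000 times and
reports the variance of the estimated mean and SD across replicates —
the argument behind a minimum cohort of ~50 participants per task.
"""

import retestkit as rk

curve = rk.sample_size_simulation(
    n_grid=(5, 10, 25, 50, 100), n_iterations=10_000, seed=0
)

print("  n   var(mean)   var(SD)     [analytic: 1/n, ~1/(2n)]")
for n, vm, vs in zip(curve.n_grid, curve.var_of_mean, curve.var_of_sd):
    print(f"{n:4d}   {vm:8.4f}   {vs:8.4f}     [{1 / n:.4f}, {1 / (2 * n):.4f}]")

print()
print(
    "By n = 50 the variance of the estimated mean is within ~0.02 and of "
    "the SD within ~0.01; doubling to n = 100 roughly halves both.  The "
    "curves flatten around 50, which is why ~50 participants per task is "
    "a reasonable minimum for estimating retest variability."
)
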