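"""Subset-"A" sizes of cABC analysis across canonical distributions.

For replicate samples of n = 1000 from each named distribution, the mean
and SD of the percentage of items assigned to subset "A" is reported,
with a one-sample signed-rank test against 41% — the analytic fixed
point of ABC analysis for uniformly distributed data.  Right-skewed laws
put fewer items in "A" (the few carry most of the value); the narrow
Gaussian sits near the identity line and puts almost half in "A".
"""

from cabc import DISTRIBUTIONS, BenchmarkSpec, run_benchmark

for name in DISTRIBUTIONS:
    rep = run_benchmark(BenchmarkSpec(name, n_items=1000, replicates=10, seed=7))
    print(f"{name:22s} |A| = {rep.mean:5.1f} ± {rep.sd:4.1f} %   "
          f"signed-rank p vs 41%: {rep.p_vs_41:.3g}")
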