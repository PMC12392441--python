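"""Replicate-averaged MW distributions at increasing scission extents.

Averages the weight-percent MW distribution of the final chain pool over
independent Monte Carlo replicates at several termination extents, and
summarizes how the mass shifts below fixed MW thresholds as scission
proceeds.  (Scaled to 20 replicates x 2000 chains so it runs in seconds;
the analyses in the test suite use 50 x 5000.)
"""

import numpy as np

from pegscission import EnsembleSpec, run_replicates

spec = EnsembleSpec.from_mw(m=2000, mn0_da=6380.0, sigma_da=400.0)

print("SiC   wt% < 2000 Da   wt% < 4000 Da   modal bin (Da)")
for sic in (1.0, 2.0, 8.0):
    dist = run_replicates(spec, sic_target=sic, n_replicates=20, base_seed=11)
    below = lambda thr: dist.mean_wt_pct[dist.bin_upper < thr].sum()
    mode = dist.bin_upper[np.argmax(dist.mean_wt_pct)]
    print(f"{sic:3.0f}   {below(2000):12.1f}   {below(4000):13.1f}   {mode:12.0f}")

print("\nWith few scissions most mass keeps the starting ~6380-Da distribution;")
print("by SiC = 8 the mass sits predominantly below 4000 Da, and the 95% band")
print("(dist.lo95 / dist.hi95) quantifies replicate-to-replicate spread.")
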