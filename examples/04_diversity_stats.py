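"""Per-class diversity statistics and the mu / Ne point estimates.

The worked example reproduces the published arithmetic: neutral divergence
of 14.2% over a 12 My split at 2 generations/year gives
mu = d / (2 T g) = 2.96e-9, and neutral diversity pi = 0.147% then gives
Ne = pi / (4 mu) = 1.24e5.
"""

import numpy as np

from popgenpipe.popgen_stats import (
    estimate_mu, estimate_ne, project_folded_sfs, site_pi, tajimas_d,
    tajimas_d_from_sfs,
)

# --- worked example from printed values -------------------------------
mu = estimate_mu(0.142, 1.2e7, 2.0)
ne = estimate_ne(0.00147, mu)
print(f"mu  = 0.142 / (2 * 1.2e7 y * 2/y)  = {mu:.3e} per bp per generation")
print(f"Ne  = 0.00147 / (4 mu)             = {ne:.3e} diploids")

# --- statistics on a small set of sites -------------------------------
rng = np.random.default_rng(0)
n = 24                                   # 12 diploids
j = rng.integers(1, 12, size=40)         # minor-allele counts at 40 SNPs
pi_sum = site_pi(j, n).sum()
print(f"\n40 segregating sites, n = {n} alleles: sum of site pi = {pi_sum:.3f}")
print(f"Tajima's D = {tajimas_d(j, n):+.3f}  (folded counts, fixed n)")

sfs = project_folded_sfs(j, np.full(j.size, n), n_proj=6)
print(f"folded SFS projected to n = 6: {np.round(sfs.counts, 2)}")
print(f"Tajima's D from the projected SFS = {tajimas_d_from_sfs(sfs):+.3f}")
print("(projection lets sites with different call rates share one spectrum)")
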