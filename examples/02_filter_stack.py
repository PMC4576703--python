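"""Run the post-call filter stack on a handful of hand-made sites and show
which rule rejects each one.

Thresholds follow the default regime: QUAL >= 23, inbreeding coefficient
F >= -0.8 (all-heterozygous sites are paralog candidates), depth within
25-300% of each sample's modal coverage, mean normalised coverage within
50-140%, and at least 3 of 12 samples called.
"""

import numpy as np

from popgenpipe.variant_io import (
    CoverageProfile, FilterConfig, SiteRecord, apply_site_filters,
    proximity_filter,
)

sites = [
    ("clean het site", 100, 50.0, [0, 1] * 6, [30] * 12),
    ("low QUAL", 200, 22.0, [0, 1] * 6, [30] * 12),
    ("all heterozygous (F = -1)", 300, 50.0, [1] * 12, [30] * 12),
    ("coverage spike", 400, 50.0, [0, 1] * 6, [200] * 12),
    ("only 2 samples called", 500, 50.0, [0, 1] + [-1] * 10, [30] * 12),
]
records = [
    SiteRecord("chr1", pos, "A", ("T",), np.array(g, dtype=np.int8),
               np.array(d), qual)
    for _, pos, qual, g, d in sites
]
coverage = CoverageProfile(np.full(12, 30))
passed, mask = apply_site_filters(records, coverage, FilterConfig())

for label, pos, *_ in sites:
    print(f"{pos:4d}  {label:28s} -> {mask.status(pos)}")

kept = proximity_filter([100, 103, 200], md=5)
print(f"\nproximity filter md=5 on {{100, 103, 200}}: keeps {[int(k) for k in kept]}")
print("(100 and 103 are 3 bp apart, so both are removed)")
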