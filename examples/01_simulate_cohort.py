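"""Simulate a 12-diploid cohort under a recent contraction and write the
input bundle (VCF, reference/outgroup FASTA, GFF3, BED, truth JSON).

The printed counts are the raw material of every downstream analysis:
segregating sites carry diversity information, the annotation defines the
selected site classes, and the truth JSON records the generative
parameters so any result can be checked against its expectation.
"""

from popgenpipe.simulate import CohortConfig, simulate_cohort, write_fixture

config = CohortConfig(L=100_000, seed=11)
cohort = simulate_cohort(config)
paths = write_fixture(cohort, "example_fixture")

print(f"simulated {config.L} bp, {cohort.n_samples} diploids")
print(f"segregating sites in the sample: {cohort.positions.size}")
print(f"exons: {len(cohort.annotation.exons)}, CNEs: {len(cohort.annotation.cnes)}")
div = sum(a != b for a, b in zip(cohort.reference, cohort.outgroup))
print(f"outgroup divergence (incl. selected sites): {div / config.L:.3%}")
for name, path in paths.items():
    print(f"  {name}: {path}")
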