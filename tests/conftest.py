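import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from popgenpipe.popgen_stats import tajimas_d
from popgenpipe.simulate import (
    CohortConfig, DemographyModel, sample_cohort, simulate_cohort,
    simulate_wright_fisher, write_fixture,
)

# Replicate-simulation study conditions shared by several tests:
# loci of 2 kb in a population of ~100-120 diploids with per-site
# theta = 4*N*mu = 0.005 and rho = theta, sampled as a 12-diploid cohort.
LOCUS_BP = 2000
N_CONSTANT = 100
MU_CONSTANT = 1.25e-5            # theta = 0.005 at N = 100
N_PAIR_ANC, N_PAIR_BOT = 120, 12
MU_PAIR = 1.04e-5                # theta = 0.005 at N = 120
BOTTLENECK_GENS = 12             # ~ one bottleneck-N of generations
N_NEUTRAL_REPS = 200
N_PAIR_REPS = 100


def _sample_minor_counts(pop, seed):
    cohort = sample_cohort(pop, 12, 0.0, seed=seed)
    ones = cohort.haplotypes.sum(axis=0)
    j = np.minimum(ones, 24 - ones)
    return j[j > 0]


@pytest.fixture(scope="session")
def neutral_replicates():
    """200 neutral constant-size loci: per-locus minor-allele counts of a
    12-diploid sample, plus Tajima's D where defined."""
    reps = []
    for seed in range(N_NEUTRAL_REPS):
        pop = simulate_wright_fisher(
            LOCUS_BP, DemographyModel.constant(N_CONSTANT),
            MU_CONSTANT, MU_CONSTANT, seed=seed)
        j = _sample_minor_counts(pop, seed)
        d = tajimas_d(j, 24) if j.size else None
        reps.append({"j": j, "D": d})
    return reps


@pytest.fixture(scope="session")
def contraction_pairs():
    """Paired loci under a constant size versus a recent 10-fold
    contraction (120 -> 12 diploids for ~N_bottleneck generations)."""
    pairs = []
    bottleneck = DemographyModel(((N_PAIR_ANC, 1), (N_PAIR_BOT, BOTTLENECK_GENS)))
    constant = DemographyModel.constant(N_PAIR_ANC)
    for seed in range(N_PAIR_REPS):
        ds = []
        for dem in (constant, bottleneck):
            pop = simulate_wright_fisher(LOCUS_BP, dem, MU_PAIR, MU_PAIR, seed=seed)
            j = _sample_minor_counts(pop, seed)
            ds.append(tajimas_d(j, 24) if j.size else None)
        if ds[0] is not None and ds[1] is not None:
            pairs.append(tuple(ds))
    return pairs


@pytest.fixture(scope="session")
def small_cohort():
    """A 60 kb simulated cohort under the default study conditions."""
    return simulate_cohort(CohortConfig(L=60_000, seed=7))


@pytest.fixture(scope="session")
def fixture_bundle(small_cohort, tmp_path_factory):
    """The small cohort written out as the VCF/FASTA/GFF3/BED bundle."""
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(small_cohort, out), small_cohort
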