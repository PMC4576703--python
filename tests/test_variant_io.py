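"""Filter stack: each rule on hand-built sites, plus the stack-wide
invariants (monotonicity, mask completeness, idempotence)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popgenpipe.variant_io import (
    CallabilityMask, CoverageProfile, FilterConfig, IndelRecord, SiteRecord,
    apply_site_filters, compute_modal_coverage, cpg_prone_mask,
    depth_histograms, indel_mask, inbreeding_coefficient, proximity_filter,
    read_vcf,
)

N_SAMPLES = 12


def make_site(pos=100, qual=100.0, genotypes=None, depths=None, f=None,
              multi=False):
    if genotypes is None:
        genotypes = [0, 1] * (N_SAMPLES // 2)
    if depths is None:
        depths = [30] * N_SAMPLES
    return SiteRecord(
        chrom="chr1", pos=pos, ref_allele="A",
        alt_alleles=("T", "G") if multi else ("T",),
        genotypes=np.array(genotypes, dtype=np.int8),
        depths=np.array(depths), qual=qual, f_coef=f, multiallelic=multi,
    )


COVERAGE = CoverageProfile(np.full(N_SAMPLES, 30))


def run_filters(records, config=None):
    return apply_site_filters(records, COVERAGE, config or FilterConfig())


def write_vcf(path, body_lines, n_samples=2):
    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=F,Number=1,Type=Float,Description="F">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i}" for i in range(n_samples)) + "\n"
    )
    path.write_text(header + "".join(l + "\n" for l in body_lines))
    return path


class TestReadVcf:
    def test_single_record(self, tmp_path):
        p = write_vcf(tmp_path / "a.vcf",
                      ["chr1\t42\t.\tA\tT\t55\tPASS\tF=0.1\tGT:DP\t0/1:20\t1/1:25"])
        records, indels, samples = read_vcf(p)
        assert len(records) == 1 and not indels
        r = records[0]
        assert (r.pos, r.ref_allele, r.alt_alleles) == (42, "A", ("T",))
        assert list(r.genotypes) == [1, 2]
        assert list(r.depths) == [20, 25]
        assert r.qual == 55 and r.f_coef == pytest.approx(0.1)

    def test_empty_body(self, tmp_path):
        p = write_vcf(tmp_path / "b.vcf", [])
        records, indels, _ = read_vcf(p)
        assert records == [] and indels == []

    def test_out_of_order_raises(self, tmp_path):
        p = write_vcf(tmp_path / "c.vcf", [
            "chr1\t100\t.\tA\tT\t55\tPASS\t.\tGT:DP\t0/1:20\t1/1:25",
            "chr1\t90\t.\tA\tT\t55\tPASS\t.\tGT:DP\t0/1:20\t1/1:25",
        ])
        with pytest.raises(ValueError, match="chr1:90"):
            read_vcf(p)

    def test_indels_routed_separately(self, tmp_path):
        p = write_vcf(tmp_path / "d.vcf", [
            "chr1\t10\t.\tACCT\tA\t55\tPASS\t.\tGT:DP\t0/1:20\t1/1:25",
            "chr1\t30\t.\tA\tATT\t55\tPASS\t.\tGT:DP\t0/1:20\t0/0:25",
            "chr1\t50\t.\tG\tC\t55\tPASS\t.\tGT:DP\t0/1:20\t0/0:25",
        ])
        records, indels, _ = read_vcf(p)
        assert [r.pos for r in records] == [50]
        assert [(i.pos, i.is_deletion, i.length) for i in indels] == \
            [(10, True, 3), (30, False, 2)]

    def test_multiallelic_flagged(self, tmp_path):
        p = write_vcf(tmp_path / "e.vcf",
                      ["chr1\t10\t.\tA\tT,G\t55\tPASS\t.\tGT:DP\t0/1:20\t0/2:25"])
        records, _, _ = read_vcf(p)
        assert records[0].multiallelic


class TestModalCoverage:
    def test_argmax(self):
        assert compute_modal_coverage([{10: 5, 20: 50, 30: 3}]).modal[0] == 20

    def test_tie_breaks_to_smaller_depth(self):
        assert compute_modal_coverage([{20: 5, 10: 5}]).modal[0] == 10

    def test_all_mass_at_zero_errors(self):
        with pytest.raises(ValueError, match="no usable coverage"):
            compute_modal_coverage([{0: 100}])

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError):
            compute_modal_coverage([{}])

    def test_histograms_from_records(self):
        recs = [make_site(pos=p, depths=[10] * 6 + [20] * 6) for p in (1, 2)]
        hists = depth_histograms(recs)
        assert hists[0] == {10: 2} and hists[-1] == {20: 2}


class TestInbreedingCoefficient:
    def test_all_heterozygous_gives_minus_one(self):
        assert inbreeding_coefficient([1] * 12) == pytest.approx(-1.0)

    def test_hardy_weinberg_proportions_give_zero(self):
        # p = 0.5, 12 samples: 3 hom-ref, 6 het, 3 hom-alt
        g = [0] * 3 + [1] * 6 + [2] * 3
        assert inbreeding_coefficient(g) == pytest.approx(0.0)

    def test_fewer_than_ten_called_is_absent(self):
        assert inbreeding_coefficient([1] * 9 + [-1] * 3) is None

    def test_monomorphic_is_absent(self):
        assert inbreeding_coefficient([0] * 12) is None


class TestSiteFilters:
    def test_low_qual_fails(self):
        passed, mask = run_filters([make_site(qual=22.0)])
        assert passed == [] and mask.status(100) == "qual"

    def test_qual_boundary_passes(self):
        passed, _ = run_filters([make_site(qual=23.0)])
        assert len(passed) == 1

    def test_all_het_fails_f(self):
        passed, mask = run_filters([make_site(genotypes=[1] * 12)])
        assert passed == [] and mask.status(100) == "F"

    def test_f_only_evaluated_with_enough_samples(self):
        g = [1] * 9 + [-1] * 3     # all het but only 9 called
        passed, _ = run_filters([make_site(genotypes=g)])
        assert len(passed) == 1

    def test_min_called(self):
        g = [0, 1] + [-1] * 10
        passed, mask = run_filters([make_site(genotypes=g)])
        assert passed == [] and mask.status(100) == "min_called"

    def test_per_sample_depth_demotes_to_missing(self):
        depths = [30] * 12
        depths[0] = 5              # < 25% of modal 30
        passed, _ = run_filters([make_site(depths=depths)])
        assert len(passed) == 1
        assert passed[0].genotypes[0] == -1
        assert np.all(passed[0].genotypes[1:] >= 0)

    def test_mean_coverage_bounds(self):
        passed, mask = run_filters([make_site(depths=[100] * 12)])
        assert passed == [] and mask.status(100) == "mean_coverage"

    def test_multiallelic_fails(self):
        passed, mask = run_filters([make_site(multi=True)])
        assert passed == [] and mask.status(100) == "multiallelic"

    def test_mask_completeness(self):
        records = [make_site(pos=p, qual=(50 if p % 2 else 10))
                   for p in range(1, 11)]
        passed, mask = run_filters(records)
        assert mask.n_pass + mask.n_fail == mask.n_considered

    def test_monotonicity_stricter_config_never_passes_more(self):
        rng = np.random.default_rng(5)
        records = [
            make_site(pos=p,
                      qual=float(rng.uniform(10, 60)),
                      genotypes=rng.choice([-1, 0, 1, 2], size=12).tolist(),
                      depths=rng.integers(3, 80, size=12).tolist())
            for p in range(1, 60)
        ]
        base = FilterConfig()
        stricter = [
            FilterConfig(min_qual=40),
            FilterConfig(min_called=8),
            FilterConfig(per_sample_cov_bounds=(0.8, 1.2)),
            FilterConfig(mean_cov_bounds=(0.9, 1.1)),
        ]
        n_base = len(run_filters(records, base)[0])
        for cfg in stricter:
            assert len(run_filters(records, cfg)[0]) <= n_base

    def test_clean_simulated_sites_all_pass(self, fixture_bundle):
        paths, cohort = fixture_bundle
        records, _, _ = read_vcf(paths["vcf"])
        profile = compute_modal_coverage(depth_histograms(records))
        wide = FilterConfig(min_qual=0, per_sample_cov_bounds=(0.0, 100.0),
                            mean_cov_bounds=(0.0, 100.0), min_called=1,
                            f_min=-10.0)
        passed, mask = apply_site_filters(records, profile, wide)
        assert len(passed) == len(records)


class TestProximityFilter:
    def test_documented_examples(self):
        assert list(proximity_filter([100, 103, 200], 5)) == [200]
        # 104-109 are exactly 5 apart, which is NOT < 5
        assert list(proximity_filter([100, 104, 109], 5)) == [109]

    def test_md_zero_is_identity(self):
        assert list(proximity_filter([1, 2, 3], 0)) == [1, 2, 3]

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            proximity_filter([5, 1], 3)

    @given(st.lists(st.integers(1, 500), min_size=0, max_size=40, unique=True),
           st.integers(0, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_matches_enumeration(self, positions, md):
        pos = sorted(positions)
        kept = proximity_filter(pos, md)
        # brute force on the original set
        expected = [p for p in pos
                    if all(abs(p - q) >= md for q in pos if q != p)]
        assert list(kept) == expected
        assert list(proximity_filter(kept, md)) == list(kept)


class TestIndelMask:
    def test_deletion_span(self):
        # deletion of 3 bases starting at 100: anchor pos 99 in VCF terms
        rec = IndelRecord("chr1", 99, "AAAA", "A")
        assert indel_mask([rec]) == {"chr1": [(99, 103)]}

    def test_insertion_span(self):
        rec = IndelRecord("chr1", 100, "A", "ATT")
        assert indel_mask([rec]) == {"chr1": [(98, 103)]}

    def test_overlapping_masks_merge(self):
        recs = [IndelRecord("chr1", 99, "AAAA", "A"),
                IndelRecord("chr1", 101, "AAA", "A")]
        assert indel_mask(recs) == {"chr1": [(99, 104)]}


class TestCpGProneMask:
    def test_acgt(self):
        # A (next C): no; C (next G): yes; G (prev C): yes; T: no
        assert list(cpg_prone_mask("ACGT")) == [False, True, True, False]

    def test_all_a_unflagged(self):
        assert not cpg_prone_mask("A" * 10).any()

    def test_union_over_sequences(self):
        # "ACA": last base is preceded by a C, so it is flagged even though
        # the reference "AAA" contributes nothing
        assert list(cpg_prone_mask("AAA", "ACA")) == [False, False, True]
        flags = cpg_prone_mask("AAA", "ACG")
        assert list(flags) == [False, True, True]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cpg_prone_mask("AAA", "AAAA")
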