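"""Variant input and the post-call site filter stack.

Reads a multi-sample VCF into lightweight site records and applies, in a
fixed order, the quality, inbreeding-coefficient, coverage, minimum-call,
proximity, indel-flank and CpG-prone filters. The outcome is a callability
mask recording, per position, either pass or the first failing reason;
every downstream denominator (accessible sites per class) is derived from
this mask.

Filter order at a site: QUAL -> inbreeding F -> per-sample depth bounds
(offending samples are set missing, not the whole site) -> mean normalised
coverage -> minimum called samples. Proximity, indel and CpG masks apply
positionally, independent of genotype content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SiteRecord",
    "IndelRecord",
    "FilterConfig",
    "CoverageProfile",
    "CallabilityMask",
    "read_variants",
    "read_vcf",
    "depth_histograms",
    "compute_modal_coverage",
    "inbreeding_coefficient",
    "apply_site_filters",
    "proximity_filter",
    "indel_mask",
    "cpg_prone_mask",
]

MISSING = -1


@dataclass
class SiteRecord:
    """One biallelic (or flagged multi-allelic) SNV site."""

    chrom: str
    pos: int                      # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: np.ndarray         # (n_samples,) dosage of first ALT, -1 missing
    depths: np.ndarray            # (n_samples,) read depth
    qual: float
    f_coef: float | None = None
    multiallelic: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)

    @property
    def n_called(self) -> int:
        return int(np.sum(self.genotypes >= 0))


@dataclass
class IndelRecord:
    chrom: str
    pos: int                      # 1-based anchor base (the base before the event)
    ref_allele: str
    alt_allele: str

    @property
    def is_deletion(self) -> bool:
        return len(self.ref_allele) > len(self.alt_allele)

    @property
    def length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-call filter stack.

    Defaults follow the filtering regime the pipeline targets: QUAL >= 23,
    inbreeding coefficient F >= -0.8 (evaluated only when >= 10 samples are
    called), per-sample depth within 25%-300% of that sample's modal
    coverage, mean normalised coverage within 50%-140%, at least 3 of 12
    samples called, and an optional proximity filter (md = 5 in the
    sensitive analyses).
    """

    min_qual: float = 23.0
    f_min: float = -0.8
    f_min_samples: int = 10
    per_sample_cov_bounds: tuple[float, float] = (0.25, 3.0)
    mean_cov_bounds: tuple[float, float] = (0.5, 1.4)
    min_called: int = 3
    proximity_md: int = 0
    cpg_exclude: bool = False

    def __post_init__(self):
        if self.per_sample_cov_bounds[0] > self.per_sample_cov_bounds[1]:
            raise ValueError("per_sample_cov_bounds out of order")
        if self.mean_cov_bounds[0] > self.mean_cov_bounds[1]:
            raise ValueError("mean_cov_bounds out of order")
        if self.proximity_md < 0:
            raise ValueError("proximity_md must be >= 0")


@dataclass
class CoverageProfile:
    """Per-sample modal coverage used to normalise depths."""

    modal: np.ndarray

    def __post_init__(self):
        self.modal = np.asarray(self.modal, dtype=float)
        if np.any(self.modal < 1):
            raise ValueError("modal coverage must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.modal.size


@dataclass
class CallabilityMask:
    """Pass/fail-with-reason status for every position considered.

    Positions not present in ``reasons`` are passing. ``n_considered`` is
    the coordinate span the mask covers (chromosome length for a pipeline
    run), so #pass + #fail = n_considered.
    """

    n_considered: int
    reasons: dict[int, str] = field(default_factory=dict)   # 1-based pos -> reason

    def status(self, pos: int) -> str:
        return self.reasons.get(pos, "pass")

    def passes(self, pos: int) -> bool:
        return pos not in self.reasons

    @property
    def n_fail(self) -> int:
        return len(self.reasons)

    @property
    def n_pass(self) -> int:
        return self.n_considered - self.n_fail

    def fail(self, pos: int, reason: str) -> None:
        # first failing reason wins
        self.reasons.setdefault(pos, reason)

    def pass_array(self, length: int | None = None) -> np.ndarray:
        """Boolean accessibility vector over 0-based positions."""
        L = length if length is not None else self.n_considered
        out = np.ones(L, dtype=bool)
        for pos in self.reasons:
            if 1 <= pos <= L:
                out[pos - 1] = False
        return out


def _parse_genotype(gt) -> int:
    # cyvcf2 genotype entry: [allele0, allele1, phased]
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return MISSING
    return int(a > 0) + int(b > 0)


def read_vcf(vcf_path) -> tuple[list[SiteRecord], list[IndelRecord], list[str]]:
    """Read a VCF into SNV site records and indel records.

    Records must be coordinate-sorted; multi-allelic SNVs are flagged (they
    later fail with reason 'multiallelic'); any record whose REF or an ALT
    is longer than one base is routed to the indel list.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    snvs: list[SiteRecord] = []
    indels: list[IndelRecord] = []
    last: dict[str, int] = {}
    for var in vcf:
        if var.CHROM in last and var.POS < last[var.CHROM]:
            raise ValueError(
                f"VCF not coordinate-sorted at {var.CHROM}:{var.POS} "
                f"(previous position {last[var.CHROM]})"
            )
        last[var.CHROM] = var.POS
        alts = tuple(a for a in var.ALT if a != "<NON_REF>")
        if len(var.REF) > 1 or any(len(a) > 1 for a in alts):
            alt = alts[0] if alts else var.REF
            indels.append(IndelRecord(var.CHROM, var.POS, var.REF, alt))
            continue
        dp = var.format("DP")
        depths = (dp[:, 0] if dp is not None else np.zeros(len(samples))).astype(np.int64)
        depths = np.where(depths < 0, 0, depths)
        genotypes = np.array([_parse_genotype(g) for g in var.genotypes], dtype=np.int8)
        f = var.INFO.get("F")
        snvs.append(
            SiteRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_alleles=alts,
                genotypes=genotypes,
                depths=depths,
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                f_coef=float(f) if f is not None else None,
                multiallelic=len(alts) > 1,
            )
        )
    return snvs, indels, samples


def read_variants(vcf_path) -> list[SiteRecord]:
    """SNV records only (see :func:`read_vcf` for the full split)."""
    return read_vcf(vcf_path)[0]


def depth_histograms(records) -> list[dict[int, int]]:
    """Per-sample depth histograms over the given records."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    n = records[0].depths.size
    hists: list[dict[int, int]] = [dict() for _ in range(n)]
    for rec in records:
        for i, d in enumerate(rec.depths):
            hists[i][int(d)] = hists[i].get(int(d), 0) + 1
    return hists


def compute_modal_coverage(histograms) -> CoverageProfile:
    """Modal (argmax) depth per sample; ties break to the smallest depth,
    which is conservative against duplicated regions. All mass at depth 0
    means the sample is unusable."""
    modal = []
    for hist in histograms:
        if not hist or sum(hist.values()) == 0:
            raise ValueError("empty depth histogram")
        best = max(sorted(hist), key=lambda d: hist[d])
        if best == 0:
            raise ValueError("no usable coverage (modal depth 0)")
        modal.append(best)
    return CoverageProfile(np.array(modal))


def inbreeding_coefficient(genotypes, min_samples: int = 10):
    """F = 1 - H_obs/H_exp from a dosage vector; None when fewer than
    ``min_samples`` are called or the site is monomorphic."""
    from .popgen_stats import inbreeding_coefficient_from_dosages

    return inbreeding_coefficient_from_dosages(genotypes, min_samples)


def apply_site_filters(records, coverage: CoverageProfile, config: FilterConfig,
                       mask: CallabilityMask | None = None):
    """Run the genotype-level filter stack over site records.

    Returns (passing records, mask). Passing records may have had
    individual samples set missing by the per-sample depth bounds. The mask
    records the first failing reason per failing site.
    """
    records = list(records)
    if records and records[0].depths.size != coverage.n_samples:
        raise ValueError("sample count mismatch between records and coverage profile")
    if mask is None:
        span = max((r.pos for r in records), default=0)
        mask = CallabilityMask(n_considered=span)
    passed: list[SiteRecord] = []
    lo, hi = config.per_sample_cov_bounds
    mlo, mhi = config.mean_cov_bounds
    for rec in records:
        if not mask.passes(rec.pos):
            continue
        if rec.multiallelic:
            mask.fail(rec.pos, "multiallelic")
            continue
        if rec.qual < config.min_qual:
            mask.fail(rec.pos, "qual")
            continue
        f = rec.f_coef
        if f is None:
            f = inbreeding_coefficient(rec.genotypes, config.f_min_samples)
        elif rec.n_called < config.f_min_samples:
            f = None
        if f is not None and f < config.f_min:
            mask.fail(rec.pos, "F")
            continue
        norm = rec.depths / coverage.modal
        bad_depth = (norm < lo) | (norm > hi)
        genotypes = np.where(bad_depth, np.int8(MISSING), rec.genotypes)
        mean_norm = float(np.mean(norm))
        if not (mlo <= mean_norm <= mhi):
            mask.fail(rec.pos, "mean_coverage")
            continue
        if int(np.sum(genotypes >= 0)) < config.min_called:
            mask.fail(rec.pos, "min_called")
            continue
        passed.append(replace(rec, genotypes=genotypes))
    return passed, mask


def proximity_filter(positions, md: int):
    """Drop every variant position that has another ORIGINAL variant
    position at distance < md (no cascade: distances are measured on the
    input set, so removals do not rescue neighbours)."""
    pos = np.asarray(positions)
    if pos.size == 0 or md <= 0:
        return pos.copy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    left = np.empty(pos.size)
    right = np.empty(pos.size)
    left[0] = np.inf
    left[1:] = pos[1:] - pos[:-1]
    right[-1] = np.inf
    right[:-1] = pos[1:] - pos[:-1]
    keep = (left >= md) & (right >= md)
    return pos[keep]


def indel_mask(indels) -> dict[str, list[tuple[int, int]]]:
    """Positions masked around indels, per chromosome, as merged 1-based
    inclusive intervals.

    A deletion of length L occupying [p, p+L-1] masks [p-1, p+L]. An
    insertion of length L between p and p+1 masks [p-L, p+1+L] (the insert
    length on each side plus one flanking base; the event has no reference
    span, so the masked span is symmetric around the insertion point).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in indels:
        L = rec.length
        if L < 0:
            raise ValueError("negative indel length")
        if rec.is_deletion:
            start = rec.pos + 1      # first deleted base (pos is the anchor)
            lo, hi = start - 1, start + L
        else:
            lo, hi = rec.pos - L, rec.pos + 1 + L
        by_chrom.setdefault(rec.chrom, []).append((max(1, lo), hi))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for lo, hi in ivs[1:]:
            if lo <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[chrom] = [tuple(iv) for iv in out]
    return merged


def cpg_prone_mask(*sequences) -> np.ndarray:
    """Flag positions preceded by a C or followed by a G in ANY of the
    given aligned sequences (hypermutable CpG context). Terminal positions
    evaluate only the neighbour that exists."""
    if not sequences:
        raise ValueError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences differ in length")
    flags = np.zeros(L, dtype=bool)
    for seq in sequences:
        arr = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype="S1")
        prev_c = np.zeros(L, dtype=bool)
        prev_c[1:] = arr[:-1] == b"C"
        next_g = np.zeros(L, dtype=bool)
        next_g[:-1] = arr[1:] == b"G"
        flags |= prev_c | next_g
    return flags
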