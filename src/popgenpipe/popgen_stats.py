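"""Per-class population-genetic statistics.

Diversity (pi), divergence from an outgroup (d), pi/d, the folded site
frequency spectrum at a fixed projected sample size, Tajima's D, block
bootstrap confidence intervals, and the mu / Ne point estimates that follow
from equating 4-fold (or other putatively neutral) diversity to 4*Ne*mu.
Also the two export encodings used by downstream demographic / DFE tools:
a 100 bp K/T/N heterozygosity encoding and a folded-SFS text file.

Conventions: pi denominators always include monomorphic accessible sites of
the class, so per-site rates are comparable across classes; j is the minor
allele count at a site with n called alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "FoldedSFS",
    "ClassSummary",
    "NeEstimate",
    "site_pi",
    "class_pi",
    "divergence",
    "major_alleles",
    "inbreeding_coefficient",
    "inbreeding_coefficient_from_dosages",
    "project_folded_sfs",
    "tajimas_d",
    "tajimas_d_from_sfs",
    "bootstrap_ci",
    "estimate_mu",
    "estimate_ne",
    "encode_psmc_input",
    "write_dfe_alpha_sfs",
    "read_dfe_alpha_sfs",
    "largest_remainder_round",
]


@dataclass
class FoldedSFS:
    """Folded allele-frequency spectrum at a fixed haploid sample size.

    ``counts[k]`` for k = 0..n_proj//2; the k = 0 bin holds monomorphic
    accessible sites. Counts are real numbers because hypergeometric
    projection distributes each site's mass over minor-allele bins.
    """

    n_proj: int
    counts: np.ndarray
    class_label: str = ""
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.n_proj // 2 + 1:
            raise ValueError("counts must have n_proj//2 + 1 bins")
        if np.any(self.counts < -1e-9):
            raise ValueError("negative SFS counts")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())


@dataclass
class ClassSummary:
    class_name: str
    n_sites: int
    pi: float
    d: float | None = None
    pi_over_d: float | None = None
    tajima_d: float | None = None
    ci_95: dict = field(default_factory=dict)


@dataclass
class NeEstimate:
    mu_hat: float
    ne_hat: float
    inputs: dict = field(default_factory=dict)


def site_pi(j, n):
    """Per-site heterozygosity 2j(n-j)/(n(n-1)) for j minor copies out of
    n called alleles. Accepts scalars or arrays."""
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("need n >= 2 called alleles")
    out = 2.0 * j * (n - j) / (n * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def class_pi(j, n, n_accessible):
    """Mean per-site diversity of a site class.

    Sum of per-site heterozygosities over the segregating sites divided by
    the total number of accessible class sites (monomorphic included).
    """
    if n_accessible <= 0:
        raise ValueError("zero accessible sites")
    j = np.asarray(j)
    if j.size == 0:
        return 0.0, int(n_accessible)
    return float(np.sum(site_pi(j, n)) / n_accessible), int(n_accessible)


def major_alleles(dosages, ref_bases, alt_bases):
    """Ingroup major allele per site from diploid dosages (-1 = missing).

    Ties between ref and alt resolve to the reference allele.
    """
    dos = np.asarray(dosages)
    called = dos >= 0
    alt_count = np.where(called, dos, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    ref_bases = np.asarray(ref_bases)
    alt_bases = np.asarray(alt_bases)
    return np.where(alt_count * 2 > n_alleles, alt_bases, ref_bases)


def divergence(ingroup_major, outgroup_bases, usable=None):
    """Per-site divergence: fraction of counted sites where the outgroup
    base differs from the ingroup major allele. Sites with no outgroup base
    (N) are dropped from numerator and denominator."""
    a = np.asarray(ingroup_major)
    b = np.asarray(outgroup_bases)
    if a.shape != b.shape:
        raise ValueError("sequence length mismatch")
    ok = (b != b"N") & (b != "N")
    if usable is not None:
        ok = ok & np.asarray(usable, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no usable sites for divergence")
    diffs = int(np.sum((a != b) & ok))
    return diffs / n, n


def inbreeding_coefficient(genotypes, min_samples: int = 10):
    """F = 1 - H_obs / H_exp at one biallelic site.

    ``genotypes`` is a sequence of diploid calls, each a pair of allele
    indices (0/1) or None for missing. Returns None when fewer than
    ``min_samples`` samples are called or the site is monomorphic
    (H_exp = 0), mirroring the behaviour of standard variant callers.
    """
    called = [g for g in genotypes if g is not None and -1 not in g]
    if len(called) < min_samples:
        return None
    alleles = np.array(called)
    p = alleles.mean()
    h_exp = 2 * p * (1 - p)
    if h_exp == 0:
        return None
    h_obs = np.mean(alleles[:, 0] != alleles[:, 1])
    return float(1.0 - h_obs / h_exp)


def inbreeding_coefficient_from_dosages(dosages, min_samples: int = 10):
    """Same as :func:`inbreeding_coefficient` for a dosage vector
    (0/1/2, -1 missing); heterozygotes are dosage-1 samples."""
    dos = np.asarray(dosages)
    called = dos[dos >= 0]
    if called.size < min_samples:
        return None
    p = called.sum() / (2 * called.size)
    h_exp = 2 * p * (1 - p)
    if h_exp == 0:
        return None
    h_obs = np.mean(called == 1)
    return float(1.0 - h_obs / h_exp)


def project_folded_sfs(j, n, n_proj: int, n_monomorphic: float = 0.0,
                       class_label: str = "") -> FoldedSFS:
    """Project variable-n sites to a common haploid size by hypergeometric
    downsampling, then fold.

    Each site with j minor alleles out of n called contributes
    P(k of n_proj | j of n) to bin min(k, n_proj - k). Sites with
    n < n_proj are skipped and counted in ``n_skipped``. ``n_monomorphic``
    is added to bin 0 (monomorphic accessible sites of the class).
    """
    if n_proj < 4:
        raise ValueError("n_proj must be >= 4")
    j = np.atleast_1d(np.asarray(j, dtype=int))
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if n.size == 1:
        n = np.full(j.shape, n[0])
    counts = np.zeros(n_proj // 2 + 1)
    counts[0] += n_monomorphic
    skipped = 0
    k = np.arange(n_proj + 1)
    folded_bin = np.minimum(k, n_proj - k)
    for jj, nn in zip(j, n):
        if nn < n_proj:
            skipped += 1
            continue
        mass = hypergeom.pmf(k, nn, jj, n_proj)
        np.add.at(counts, folded_bin, mass)
    return FoldedSFS(n_proj=n_proj, counts=counts, class_label=class_label,
                     n_skipped=skipped)


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(j, n: int) -> float:
    """Tajima's D from minor-allele counts ``j`` at a fixed haploid sample
    size ``n``. Raises on zero segregating sites (D is undefined there)."""
    if n < 4:
        raise ValueError("need n >= 4")
    j = np.asarray(j)
    j = j[(j > 0) & (j < n)]
    S = j.size
    if S == 0:
        raise ValueError("Tajima's D undefined with S = 0 segregating sites")
    pi_sum = float(np.sum(site_pi(j, n)))
    a1, e1, e2 = _tajima_constants(n)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d_from_sfs(sfs: FoldedSFS) -> float:
    """Tajima's D from a folded spectrum (bin 0 ignored); fractional counts
    from projection are used as weights."""
    n = sfs.n_proj
    if n < 4:
        raise ValueError("need n_proj >= 4")
    k = np.arange(1, sfs.counts.size)
    w = sfs.counts[1:]
    S = float(w.sum())
    if S <= 0:
        raise ValueError("Tajima's D undefined with S = 0 segregating sites")
    pi_sum = float(np.sum(w * site_pi(k, n)))
    a1, e1, e2 = _tajima_constants(n)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def bootstrap_ci(statistic_fn, units, n_boot: int = 1000, seed: int = 0,
                 max_undefined_frac: float = 0.10):
    """Percentile bootstrap interval (2.5%, 97.5%) for a statistic over
    resampling units (transcripts for exonic classes, nonempty 1 Mb windows
    for CNE classes).

    ``statistic_fn`` maps a list of units to a float; units are resampled
    with replacement. Errors out when the statistic is undefined in more
    than ``max_undefined_frac`` of replicates.
    """
    units = list(units)
    if len(units) < 2:
        raise ValueError("need >= 2 resampling units")
    rng = np.random.default_rng(seed)
    vals = []
    n_bad = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(units), size=len(units))
        try:
            v = statistic_fn([units[i] for i in idx])
        except (ValueError, ZeroDivisionError):
            v = np.nan
        if v is None or not np.isfinite(v):
            n_bad += 1
        else:
            vals.append(v)
    if n_bad > max_undefined_frac * n_boot:
        raise ValueError(f"statistic undefined in {n_bad}/{n_boot} bootstrap replicates")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_mu(d: float, t_split_years: float, gens_per_year: float) -> float:
    """Mutation rate per bp per generation from neutral divergence ``d``
    accumulated over ``2 * t_split_years * gens_per_year`` generations
    (two lineages since the split)."""
    if d <= 0 or t_split_years <= 0 or gens_per_year <= 0:
        raise ValueError("all inputs must be > 0")
    return d / (2.0 * t_split_years * gens_per_year)


def estimate_ne(pi: float, mu: float) -> float:
    """Effective population size from pi = 4*Ne*mu at neutral sites."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (4.0 * mu)


def encode_psmc_input(het, called, bin_bp: int = 100,
                      min_called_frac: float = 0.1,
                      chrom: str = "chr1", width: int = 60) -> str:
    """Encode one diploid genome as the 100 bp K/T/N character sequence
    demographic-inference tools consume.

    Per bin: 'N' if fewer than ``min_called_frac`` of the bin's sites are
    called, else 'K' if the bin contains at least one heterozygous call,
    else 'T'. Output is a FASTA-like record wrapped at ``width`` characters.
    Genotype-quality and cohort-calledness filters are expected to have been
    applied upstream when building ``called``.
    """
    if bin_bp < 1:
        raise ValueError("bin size must be >= 1")
    het = np.asarray(het, dtype=bool)
    called = np.asarray(called, dtype=bool)
    if het.shape != called.shape:
        raise ValueError("het and called must have equal length")
    L = het.size
    n_bins = (L + bin_bp - 1) // bin_bp
    chars = []
    for b in range(n_bins):
        s, e = b * bin_bp, min((b + 1) * bin_bp, L)
        frac = called[s:e].mean() if e > s else 0.0
        if frac < min_called_frac:
            chars.append("N")
        elif np.any(het[s:e] & called[s:e]):
            chars.append("K")
        else:
            chars.append("T")
    seq = "".join(chars)
    lines = [f">{chrom}"]
    lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


def largest_remainder_round(values) -> np.ndarray:
    """Round a nonnegative vector to integers preserving the (rounded)
    total: floor everything, then hand out the remaining units to the
    largest fractional parts."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative counts")
    floors = np.floor(v).astype(int)
    remainder = int(round(v.sum())) - int(floors.sum())
    if remainder > 0:
        order = np.argsort(-(v - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors


def write_dfe_alpha_sfs(selected: FoldedSFS, neutral: FoldedSFS,
                        divergences: dict, path) -> None:
    """Write the paired-spectra text input of the DFE estimation toolchain.

    Layout: a dataset-count line ('1'), the haploid sample size, the neutral
    then the selected folded count vector (padded with zeros to length
    n_proj + 1, as folded spectra are conventionally laid out), then a
    divergence block with one ``class n_sites n_diffs`` line per entry of
    ``divergences`` (mapping class -> (d, n_sites)). Counts are integers via
    largest-remainder rounding.
    """
    import warnings

    if selected.n_proj != neutral.n_proj:
        raise ValueError("selected and neutral spectra differ in n_proj")
    if selected.counts[1:].sum() == 0:
        warnings.warn("selected SFS has no segregating sites")
    n = selected.n_proj

    def padded(sfs: FoldedSFS) -> np.ndarray:
        out = np.zeros(n + 1, dtype=int)
        out[: sfs.counts.size] = largest_remainder_round(sfs.counts)
        return out

    with open(path, "w") as fh:
        fh.write("1\n")
        fh.write(f"{n}\n")
        for sfs in (neutral, selected):
            fh.write(" ".join(str(int(c)) for c in padded(sfs)) + "\n")
        for name, (d, n_sites) in divergences.items():
            fh.write(f"{name} {int(n_sites)} {int(round(d * n_sites))}\n")


def read_dfe_alpha_sfs(path):
    """Round-trip reader for :func:`write_dfe_alpha_sfs`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[1])
    neutral = np.array([float(x) for x in lines[2].split()])
    selected = np.array([float(x) for x in lines[3].split()])
    divergences = {}
    for ln in lines[4:]:
        name, n_sites, diffs = ln.split()
        n_sites = int(n_sites)
        divergences[name] = (int(diffs) / n_sites if n_sites else 0.0, n_sites)
    return {"n_proj": n, "neutral": neutral, "selected": selected,
            "divergences": divergences}
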