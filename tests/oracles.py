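"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written the slow, obvious way (pairwise
loops, exhaustive enumeration, textbook formulas transcribed directly) and
shares no code with the package, so agreement is meaningful.
"""

from itertools import combinations

import numpy as np


def brute_force_pi(haplotype_columns, n_accessible):
    """Mean pairwise difference per site: count differences over every
    unordered haplotype pair at every site, divide by pairs and by
    accessible sites. ``haplotype_columns`` is (n_hap, S) 0/1."""
    H = np.asarray(haplotype_columns)
    n = H.shape[0]
    total = 0
    for a, b in combinations(range(n), 2):
        total += int(np.sum(H[a] != H[b]))
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / n_accessible


def brute_force_site_pi(j, n):
    """Fraction of unordered allele pairs that differ at one site with j
    copies of one allele out of n, counted explicitly."""
    alleles = [1] * j + [0] * (n - j)
    diff = sum(1 for a, b in combinations(alleles, 2) if a != b)
    return diff / (n * (n - 1) / 2)


def textbook_tajimas_d(counts, n):
    """Tajima's D transcribed from the 1989 definitions: theta_pi from
    mean pairwise differences, theta_W = S/a1, variance via b1,b2,c1,c2,
    e1,e2."""
    counts = [c for c in counts if 0 < c < n]
    S = len(counts)
    if S == 0:
        raise ValueError("undefined")
    theta_pi = sum(brute_force_site_pi(j, n) for j in counts)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (theta_pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))


def enumerate_projection(j, n, n_proj):
    """Distribution of minor-allele counts after downsampling to n_proj,
    by exhaustive enumeration of all C(n, n_proj) subsamples."""
    alleles = [1] * j + [0] * (n - j)
    bins = np.zeros(n_proj // 2 + 1)
    total = 0
    for sub in combinations(range(n), n_proj):
        k = sum(alleles[i] for i in sub)
        bins[min(k, n_proj - k)] += 1
        total += 1
    return bins / total


def weighted_ols_slope(x, y, w):
    """Weighted least squares slope/intercept via explicit normal
    equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = w.sum()
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    slope = (sw * sxy - sx * sy) / (sw * sxx - sx * sx)
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def degeneracy_via_translation(codon, pos):
    """Synonymous-substitution count at one codon position via Biopython
    translation of every single-base substitution."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if str(Seq(alt).translate()) == aa:
            syn += 1
    return syn
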