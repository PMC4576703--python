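"""Genotype-based linkage-disequilibrium decay and its curve fits.

r² between two sites is the squared Pearson correlation of their diploid
dosage vectors over samples called at both sites (the genotype-based
estimator that needs no phasing). Pairs are pooled into 20 bp distance
bins around focal SNPs, and the decay of the per-bin mean r² with distance
is summarised by an offset exponential

    f(x) = (a - c) * exp(-x / b) + c

or an offset stretched exponential

    g(x) = (a - c) * exp(-(x / b)^d) + c,  0 < d <= 1,

whose characteristic length b is the biologically interesting parameter.
The offset c has a theoretical sampling floor of 1/(n-1) for n diploids.
Stretched-exponential fits are run from a deterministic multistart grid
because these fits are notoriously sensitive to initialisation; refits
with d pinned at 0.5 make b comparable across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LDCurve",
    "StretchedExpFit",
    "genotype_r2",
    "ld_decay_curve",
    "theoretical_r2_floor",
    "fit_offset_exponential",
    "fit_stretched_exponential",
    "stretched_exponential",
]

MISSING = -1


@dataclass
class LDCurve:
    bin_bp: int
    max_distance: int
    table: pd.DataFrame            # bin_start, bin_end, mean_r2, pair_count
    focal_set: str = "all"
    n_samples: int = 0
    n_skipped_pairs: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class StretchedExpFit:
    a: float
    b: float
    c: float
    d_stretch: float
    fixed_d: bool
    residual_ss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return stretched_exponential(np.asarray(x, dtype=float),
                                     self.a, self.b, self.c, self.d_stretch)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d_stretch,
                "fixed_d": self.fixed_d, "residual_ss": self.residual_ss,
                "converged": self.converged}


def stretched_exponential(x, a, b, c, d):
    return (a - c) * np.exp(-np.power(np.maximum(x, 0.0) / b, d)) + c


def genotype_r2(dosages_a, dosages_b):
    """Squared Pearson correlation of two dosage vectors over the samples
    called in both; None (skipped) when fewer than two complete pairs or
    either vector is constant over them."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    a, b = a[ok], b[ok]
    va = a - a.mean()
    vb = b - b.mean()
    ssa = np.dot(va, va)
    ssb = np.dot(vb, vb)
    if ssa == 0 or ssb == 0:
        return None
    cov = np.dot(va, vb)
    return float(cov * cov / (ssa * ssb))


def theoretical_r2_floor(n_samples: int) -> float:
    """Sampling floor of mean r² between unlinked sites: 1/(n-1)."""
    if n_samples < 2:
        raise ValueError("need n >= 2 samples")
    return 1.0 / (n_samples - 1)


def ld_decay_curve(genotypes, positions, focal_positions=None,
                   max_distance: int = 40_000, bin_bp: int = 20,
                   n_max: int | None = None, seed: int = 0,
                   focal_set: str = "all") -> LDCurve:
    """Mean r² per distance bin around focal SNPs.

    ``genotypes`` is (n_samples, S) dosages (-1 missing) at sorted
    ``positions``. With ``focal_set='all'`` every unordered pair within
    ``max_distance`` is counted once (partners downstream of the focal
    SNP); for a restricted focal set each focal SNP pairs with partners on
    both sides, and a pair of two focal SNPs is still counted once. If one
    focal SNP's window holds more than ``n_max`` pairs, they are subsampled
    uniformly without replacement.
    """
    G = np.asarray(genotypes)
    pos = np.asarray(positions)
    if pos.size != G.shape[1]:
        raise ValueError("positions do not match genotype columns")
    if focal_positions is None:
        focal_idx = np.arange(pos.size)
    else:
        focal_idx = np.searchsorted(pos, np.asarray(focal_positions))
        if not np.all(pos[np.minimum(focal_idx, pos.size - 1)]
                      == np.asarray(focal_positions)):
            raise ValueError("focal positions must be a subset of SNP positions")
    if focal_idx.size == 0:
        raise ValueError("no focal SNPs")
    rng = np.random.default_rng(seed)
    restricted = focal_set != "all"
    focal_mask = np.zeros(pos.size, dtype=bool)
    focal_mask[focal_idx] = True

    n_bins = int(np.ceil(max_distance / bin_bp))
    r2_sum = np.zeros(n_bins)
    pair_count = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0

    Gf = G.astype(float)
    called = G != MISSING

    for fi in focal_idx:
        lo = np.searchsorted(pos, pos[fi] - max_distance, side="left")
        hi = np.searchsorted(pos, pos[fi] + max_distance, side="right")
        if restricted:
            partners = np.concatenate([np.arange(lo, fi), np.arange(fi + 1, hi)])
            # focal-focal pair appears in both windows: keep it only from
            # the lower-index focal SNP
            partners = partners[~(focal_mask[partners] & (partners < fi))]
        else:
            partners = np.arange(fi + 1, hi)
        if partners.size == 0:
            continue
        if n_max is not None and partners.size > n_max:
            partners = rng.choice(partners, size=n_max, replace=False)
        for pj in partners:
            r2 = _pair_r2(Gf, called, fi, pj)
            if r2 is None:
                n_skipped += 1
                continue
            dist = abs(int(pos[pj]) - int(pos[fi]))
            if dist < 1:
                continue
            b = (dist - 1) // bin_bp
            r2_sum[b] += r2
            pair_count[b] += 1

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(pair_count > 0, r2_sum / np.maximum(pair_count, 1), np.nan)
    table = pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_bp,
        "bin_end": (np.arange(n_bins) + 1) * bin_bp,
        "mean_r2": mean_r2,
        "pair_count": pair_count,
    })
    return LDCurve(bin_bp, max_distance, table, focal_set=focal_set,
                   n_samples=G.shape[0], n_skipped_pairs=n_skipped)


def _pair_r2(Gf, called, i, j):
    ok = called[:, i] & called[:, j]
    if ok.sum() < 2:
        return None
    a = Gf[ok, i]
    b = Gf[ok, j]
    va = a - a.mean()
    vb = b - b.mean()
    ssa = np.dot(va, va)
    ssb = np.dot(vb, vb)
    if ssa == 0 or ssb == 0:
        return None
    cov = np.dot(va, vb)
    return cov * cov / (ssa * ssb)


def _curve_data(curve: LDCurve):
    t = curve.table
    w = t["pair_count"].to_numpy(dtype=float)
    sel = w > 0
    x = ((t["bin_start"].to_numpy() + t["bin_end"].to_numpy()) / 2.0)[sel]
    y = t["mean_r2"].to_numpy(dtype=float)[sel]
    return x, y, w[sel]


def _fit(x, y, w, d_fix, starts, max_nfev=2000):
    sw = np.sqrt(w / w.sum())
    best = None
    # identifiability bounds: the offset cannot exceed the observed curve
    # maximum, and b far beyond the data span is indistinguishable from a
    # linear trend
    y_max = float(np.max(y))
    a_hi = max(1.0, 1.5 * y_max)
    c_hi = max(y_max, 1e-6)
    logb_hi = np.log(10.0 * float(np.max(x)))

    def make_resid(d_val):
        if d_val is None:
            def resid(p):
                a, logb, c, d = p
                return sw * (stretched_exponential(x, a, np.exp(logb), c, d) - y)
            return resid

        def resid(p):
            a, logb, c = p
            return sw * (stretched_exponential(x, a, np.exp(logb), c, d_val) - y)
        return resid

    for b0, d0 in starts:
        a0 = max(float(y[0]), 1e-3)
        c0 = max(float(np.mean(y[-max(3, len(y) // 10):])), 1e-6)
        if d_fix is None:
            p0 = [a0, np.log(b0), c0, d0]
            lb = [0.0, np.log(1e-2), 0.0, 1e-3]
            ub = [a_hi, logb_hi, c_hi, 1.0]
        else:
            p0 = [a0, np.log(b0), c0]
            lb = [0.0, np.log(1e-2), 0.0]
            ub = [a_hi, logb_hi, c_hi]
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(make_resid(d_fix), p0, bounds=(lb, ub),
                                max_nfev=max_nfev)
        except Exception:
            continue
        ss = float(2 * res.cost)
        if best is None or ss < best[0]:
            best = (ss, res)
    return best


_B_GRID = (100.0, 300.0, 1000.0, 3000.0, 10000.0)
_D_GRID = (0.3, 0.5, 0.7, 0.9)


def fit_offset_exponential(curve: LDCurve) -> StretchedExpFit:
    """Weighted least-squares fit of f(x) = (a-c) exp(-x/b) + c."""
    x, y, w = _curve_data(curve)
    if x.size < 4:
        raise ValueError("need >= 4 nonempty bins")
    best = _fit(x, y, w, d_fix=1.0, starts=[(b, None) for b in _B_GRID])
    if best is None:
        return StretchedExpFit(np.nan, np.nan, np.nan, 1.0, True, np.inf, False)
    ss, res = best
    a, logb, c = res.x
    return StretchedExpFit(float(a), float(np.exp(logb)), float(c), 1.0,
                           True, ss, bool(res.success))


def fit_stretched_exponential(curve: LDCurve,
                              fix_d: float | None = None) -> StretchedExpFit:
    """Bounded weighted fit of g(x) = (a-c) exp(-(x/b)^d) + c with
    0 < d <= 1, from a deterministic multistart grid over (b, d); with
    ``fix_d`` the stretch exponent is pinned (d = 0.5 makes b directly
    comparable across cohorts)."""
    x, y, w = _curve_data(curve)
    need = 4 if fix_d is not None else 5
    if x.size < need:
        raise ValueError(f"need >= {need} nonempty bins")
    if fix_d is not None and not (0 < fix_d <= 1):
        raise ValueError("fix_d must be in (0, 1]")
    if fix_d is None:
        starts = [(b, d) for b in _B_GRID for d in _D_GRID]
    else:
        starts = [(b, fix_d) for b in _B_GRID]
    best = _fit(x, y, w, d_fix=fix_d, starts=starts)
    if best is None:
        return StretchedExpFit(np.nan, np.nan, np.nan,
                               fix_d if fix_d else np.nan,
                               fix_d is not None, np.inf, False)
    ss, res = best
    if fix_d is None:
        a, logb, c, d = res.x
    else:
        a, logb, c = res.x
        d = fix_d
    return StretchedExpFit(float(a), float(np.exp(logb)), float(c), float(d),
                           fix_d is not None, ss, bool(res.success))
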