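"""Distance-binned diversity/divergence profiles around features.

Each eligible site is counted once, in the bin of its distance to the
NEAREST feature (exon or CNE). Exon-flank profiles use 1 kb bins out to
100 kb; CNE-flank profiles 100 bp bins out to 5-20 kb. The module also
builds the CNE-to-nearest-exon distance kernel and convolves ("blurs") an
exon-flank profile with it — quantifying how much of the diversity dip in
CNE flanks is explained by CNEs clustering near exons — and fits the
far-field (5-20 kb) slope by weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlankProfile",
    "DistanceKernel",
    "nearest_feature_distance",
    "bin_flank_statistics",
    "cne_exon_distance_kernel",
    "convolve_profile",
    "fit_far_slope",
]


@dataclass
class FlankProfile:
    """Per-distance-bin statistics. Bin b covers distances
    (b*bin_bp, (b+1)*bin_bp]; a site at distance 1 lands in bin 0."""

    feature_type: str
    bin_bp: int
    max_distance: int
    table: pd.DataFrame     # columns: bin_start, bin_end, pi, d, pi_over_d, n_sites

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DistanceKernel:
    """Normalised distribution of CNE-to-nearest-exon distances over
    100 bp bins, used as a convolution kernel."""

    weights: np.ndarray
    bin_bp: int = 100

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("kernel weights must be >= 0")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"kernel weights must sum to 1 (got {total})")


def _merged_arrays(features):
    from .site_classes import merge_intervals

    ivs = merge_intervals(features)
    if not ivs:
        raise ValueError("empty feature set")
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    return starts, ends


def nearest_feature_distance(positions, features) -> np.ndarray:
    """Base-pair gap from each 0-based position to the closest feature
    base; 0 inside a feature."""
    starts, ends = _merged_arrays(features)
    pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    idx = np.searchsorted(ends, pos, side="right")   # nearest feature at/after
    dist_right = np.where(idx < starts.size, starts[np.minimum(idx, starts.size - 1)] - pos,
                          np.iinfo(np.int64).max)
    inside = (idx < starts.size) & (pos >= starts[np.minimum(idx, starts.size - 1)])
    prev = idx - 1
    dist_left = np.where(prev >= 0, pos - (ends[np.maximum(prev, 0)] - 1),
                         np.iinfo(np.int64).max)
    d = np.minimum(np.maximum(dist_right, 0), np.maximum(dist_left, 0))
    d = np.where(inside, 0, d)
    return d if np.ndim(positions) else int(d[0])


def bin_flank_statistics(site_positions, site_pi_vals, site_div, features,
                         bin_bp: int, max_distance: int,
                         feature_type: str = "exon") -> FlankProfile:
    """Bin per-site statistics by distance to the nearest feature.

    ``site_pi_vals`` is each site's per-site heterozygosity contribution
    (0 for monomorphic accessible sites); ``site_div`` is 1 where the
    outgroup base mismatches the ingroup major allele, 0 where it matches,
    NaN where no outgroup base exists. Sites at distance 0 (inside a
    feature) or beyond ``max_distance`` are not counted; callers exclude
    sites belonging to other analysis classes beforehand.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    pos = np.asarray(site_positions)
    pis = np.asarray(site_pi_vals, dtype=float)
    div = np.asarray(site_div, dtype=float)
    dist = nearest_feature_distance(pos, features)
    keep = (dist >= 1) & (dist <= max_distance)
    pos, pis, div, dist = pos[keep], pis[keep], div[keep], dist[keep]
    bins = (dist - 1) // bin_bp
    n_bins = int(np.ceil(max_distance / bin_bp))
    n_sites = np.bincount(bins, minlength=n_bins).astype(float)
    pi_sum = np.bincount(bins, weights=pis, minlength=n_bins)
    has_out = ~np.isnan(div)
    d_sites = np.bincount(bins[has_out], minlength=n_bins).astype(float)
    d_sum = np.bincount(bins[has_out], weights=div[has_out], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_sites > 0, pi_sum / np.maximum(n_sites, 1), np.nan)
        d = np.where(d_sites > 0, d_sum / np.maximum(d_sites, 1), np.nan)
        pi_over_d = np.where((d > 0), pi / d, np.nan)
    table = pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_bp,
        "bin_end": (np.arange(n_bins) + 1) * bin_bp,
        "pi": pi,
        "d": d,
        "pi_over_d": pi_over_d,
        "n_sites": n_sites.astype(int),
    })
    return FlankProfile(feature_type, bin_bp, max_distance, table)


def cne_exon_distance_kernel(cnes, exons, cap: int = 200_000,
                             bin_bp: int = 100) -> DistanceKernel:
    """Normalised histogram (100 bp bins up to ``cap``) of each CNE's
    edge-to-edge gap to its nearest exon; CNEs farther than the cap are
    dropped before normalisation."""
    from .site_classes import merge_intervals

    cne_iv = merge_intervals(cnes)
    if not cne_iv:
        raise ValueError("empty CNE set")
    starts = np.array([s for s, _ in cne_iv])
    ends = np.array([e for _, e in cne_iv])
    d_start = nearest_feature_distance(starts, exons)
    d_end = nearest_feature_distance(ends - 1, exons)
    dist = np.minimum(d_start, d_end)
    dist = dist[dist <= cap]
    if dist.size == 0:
        raise ValueError("all CNEs beyond the distance cap")
    n_bins = cap // bin_bp
    bins = np.minimum(np.maximum(dist - 1, 0) // bin_bp, n_bins - 1)
    weights = np.bincount(bins, minlength=n_bins).astype(float)
    return DistanceKernel(weights / weights.sum(), bin_bp)


def convolve_profile(values, kernel: DistanceKernel,
                     pad_value: float | None = None,
                     pad_range_bins: tuple[int, int] = (600, 1000)) -> np.ndarray:
    """Blur a 100 bp-binned profile with the distance kernel.

    out[i] = sum_k kernel[k] * in[i + k], with the input padded on the
    right by the kernel's full width. The pad value defaults to the mean of
    the profile over ``pad_range_bins`` (60-100 kb for 100 bp bins); output
    length equals input length.
    """
    vals = np.asarray(values, dtype=float)
    w = kernel.weights
    if pad_value is None:
        lo, hi = pad_range_bins
        window = vals[lo:hi]
        window = window[~np.isnan(window)]
        if window.size == 0:
            raise ValueError("cannot compute pad value: empty pad range")
        pad_value = float(window.mean())
    padded = np.concatenate([vals, np.full(w.size, pad_value)])
    out = np.empty(vals.size)
    for i in range(vals.size):
        out[i] = np.dot(w, padded[i:i + w.size])
    return out


def fit_far_slope(profile: FlankProfile, window: tuple[int, int] = (5000, 20000),
                  column: str = "pi"):
    """Weighted (by n_sites) OLS of per-bin statistic on bin-midpoint
    distance over the given window. Returns (slope per bp, intercept,
    stderr of slope)."""
    t = profile.table
    mid = (t["bin_start"].to_numpy() + t["bin_end"].to_numpy()) / 2.0
    y = t[column].to_numpy(dtype=float)
    w = t["n_sites"].to_numpy(dtype=float)
    sel = (t["bin_end"].to_numpy() > window[0]) & (t["bin_start"].to_numpy() < window[1])
    sel &= (w > 0) & ~np.isnan(y)
    if sel.sum() < 3:
        raise ValueError("need >= 3 nonempty bins in fitting window")
    x, y, w = mid[sel], y[sel], w[sel]
    X = np.column_stack([x, np.ones_like(x)])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    sigma2 = np.sum(w * resid**2) / (np.sum(w) * dof / x.size)
    cov = np.linalg.inv(WX.T @ X) * sigma2
    return float(beta[0]), float(beta[1]), float(np.sqrt(max(cov[0, 0], 0.0)))
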