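"""Ensemble analytics: distance-vs-genomic-distance profiles and spread summaries.

Compact, poorly expressed chromatin stretches occupy less space than open,
highly expressed ones; comparing the mean-square Euclidean distance
between bead pairs as a function of their genomic separation makes that
difference quantitative, and boxplot summaries across an ensemble of
reconstructions show whether it is systematic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import Chain

__all__ = ["MSDProfile", "BoxplotSummary", "msd_profile", "ensemble_summary", "compare_regions"]


@dataclass(frozen=True)
class MSDProfile:
    """Mean-square distance (nm^2) per genomic offset (bp), offsets increasing."""

    genomic_distance: np.ndarray
    mean_square_distance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "genomic_distance", np.asarray(self.genomic_distance))
        object.__setattr__(
            self, "mean_square_distance", np.asarray(self.mean_square_distance, dtype=float)
        )
        if np.any(np.diff(self.genomic_distance) <= 0):
            raise ValueError("genomic offsets must be strictly increasing")
        if np.any(self.mean_square_distance < 0):
            raise ValueError("mean-square distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genomic_distance_bp": self.genomic_distance,
                "msd_nm2": self.mean_square_distance,
            }
        )


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number spread summary with Tukey whiskers.

    The box spans the second and third quartiles (q1..q3); whiskers extend
    to the most extreme data points within 1.5 x IQR of the box edges;
    points beyond are outliers; the mean is reported separately.
    """

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float
    outliers: tuple[float, ...]

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def msd_profile(config: Chain, bin_range: tuple[int, int], resolution_bp: int) -> MSDProfile:
    """Per-offset mean of squared centroid distances within a bead range.

    For each genomic offset s (in bins), averages ||x_i - x_{i+s}||^2 over
    all in-range pairs; offsets are reported in bp (s * resolution_bp).
    Centroids only -- arm points are a modelling device, not loci.
    """
    a, b = bin_range
    if not (0 <= a < b <= config.n_beads):
        raise ValueError(f"bin range [{a}, {b}) invalid for {config.n_beads} beads")
    if b - a < 2:
        raise ValueError("range must contain at least 2 beads")
    cent = config.centroids[a:b]
    n = b - a
    offsets = np.arange(1, n)
    msd = np.empty(n - 1)
    for s in offsets:
        diff = cent[s:] - cent[:-s]
        msd[s - 1] = float(np.mean(np.sum(diff * diff, axis=1)))
    return MSDProfile(offsets * resolution_bp, msd)


def ensemble_summary(values) -> BoxplotSummary:
    """Boxplot statistics under the linear-interpolation quantile rule."""
    vals = np.asarray(list(values), dtype=float)
    if len(vals) < 4:
        raise ValueError("need at least 4 values for a boxplot summary")
    q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(vals[(vals < lo_fence) | (vals > hi_fence)]))
    return BoxplotSummary(
        float(q1), float(med), float(q3),
        float(inside.min()), float(inside.max()),
        float(vals.mean()), outliers,
    )


def compare_regions(
    ensemble: list[Chain],
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    resolution_bp: int,
) -> pd.DataFrame:
    """Per-offset spread summaries of two regions across an ensemble.

    For every genomic offset, the per-structure mean-square distance is
    computed within each region, and the distribution of those values over
    the ensemble is summarised as a boxplot row.  Output is tidy
    (region, offset_bp, q1, median, q3, whiskers, mean, n_outliers), ready
    for side-by-side plotting.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    n_beads = ensemble[0].n_beads
    for ch in ensemble:
        if ch.n_beads != n_beads:
            raise ValueError("ensemble members have mismatched lengths")
    rows = []
    for name, region in (("a", region_a), ("b", region_b)):
        profiles = [msd_profile(ch, region, resolution_bp) for ch in ensemble]
        offsets = profiles[0].genomic_distance
        for k, off in enumerate(offsets):
            values = [p.mean_square_distance[k] for p in profiles]
            if len(values) >= 4:
                s = ensemble_summary(values)
                rows.append(
                    {
                        "region": name, "offset_bp": int(off),
                        "q1": s.q1, "median": s.median, "q3": s.q3,
                        "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                        "mean": s.mean, "n_outliers": len(s.outliers),
                    }
                )
            else:
                arr = np.asarray(values)
                rows.append(
                    {
                        "region": name, "offset_bp": int(off),
                        "q1": float(np.percentile(arr, 25)),
                        "median": float(np.percentile(arr, 50)),
                        "q3": float(np.percentile(arr, 75)),
                        "whisker_low": float(arr.min()),
                        "whisker_high": float(arr.max()),
                        "mean": float(arr.mean()), "n_outliers": 0,
                    }
                )
    return pd.DataFrame(rows)
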