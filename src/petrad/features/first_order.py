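"""First-order (histogram) statistics of the VOI intensity distribution.

The 14 features depend only on the multiset of masked voxel values. Entropy
and uniformity are computed from a histogram with a fixed bin width (default
0.1 SUV, the same discretization used for the texture matrices), with bins
anchored at the VOI minimum. Moments use the population convention (N in the
denominator); kurtosis is non-excess (a Gaussian scores 3).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["FIRST_ORDER_NAMES", "first_order_features", "DegenerateFeatureWarning"]

FIRST_ORDER_NAMES = [
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "std",
    "uniformity",
    "variance",
]


class DegenerateFeatureWarning(UserWarning):
    """Raised when a feature is undefined on the input and a limit is used."""


def intensity_histogram(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Normalized histogram with bins of ``bin_width`` anchored at the minimum."""
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64)
    counts = np.bincount(levels)
    return counts / counts.sum()


def first_order_features(values, bin_width: float = 0.1) -> dict[str, float]:
    """Compute the 14 first-order statistics of the masked voxel values.

    Parameters
    ----------
    values : 1D array of masked voxel intensities (or an object with a
        ``masked_values`` attribute, e.g. a :class:`~petrad.volume_io.VOI`).
    bin_width : histogram bin width for entropy/uniformity, in intensity units.
    """
    if hasattr(values, "masked_values"):
        values = values.masked_values
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty VOI: no masked voxels")
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")

    n = x.size
    mean = x.mean()
    # a constant sample has variance exactly 0 (by definition, not by
    # floating-point accumulation)
    degenerate = x.max() == x.min()
    var = 0.0 if degenerate else x.var()  # population variance
    std = np.sqrt(var)

    if not degenerate:
        skewness = np.mean((x - mean) ** 3) / std**3
        kurtosis = np.mean((x - mean) ** 4) / var**2
    else:
        warnings.warn(
            "zero-variance VOI: skewness and kurtosis undefined, returning 0",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
        skewness = 0.0
        kurtosis = 0.0

    p = intensity_histogram(x, bin_width)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())

    return {
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "kurtosis": float(kurtosis),
        "maximum": float(x.max()),
        "mean": float(mean),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "skewness": float(skewness),
        "std": float(std),
        "uniformity": uniformity,
        "variance": float(var),
    }
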