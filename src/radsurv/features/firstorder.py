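"""The 18 first-order (intensity histogram) features."""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, VOIMask
from .discretize import DiscretizationSpec, discretize

__all__ = ["FIRST_ORDER_NAMES", "compute_first_order"]

FIRST_ORDER_NAMES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Uniformity",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
)


def compute_first_order(
    vol: ImageVolume, mask: VOIMask, disc: DiscretizationSpec
) -> dict[str, float]:
    """Intensity statistics of the masked region.

    Variance is the population moment (ddof=0); kurtosis is the Pearson
    (non-excess) form m4/m2^2; Entropy (bits) and Uniformity are computed
    on the discretized histogram. A constant region yields Variance 0,
    Entropy 0, Uniformity 1 and Skewness/Kurtosis 0 by convention.
    """
    mask.check_aligned(vol)
    x = vol.values[mask.values]
    if x.size == 0:
        raise ValueError("empty mask: no voxels to compute first-order features on")

    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        centered = x - mean
        m2 = float((centered**2).mean())
        skew = float((centered**3).mean()) / m2**1.5
        kurt = float((centered**4).mean()) / m2**2
    else:
        skew = kurt = 0.0

    levels = discretize(x, disc)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(vol.voxel_volume * (x**2).sum()),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
    }
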