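"""First-order (histogram) features: 18 statistics of region intensities.

Entropy and Uniformity are computed on the fixed-bin-width discretized
histogram; everything else on raw intensities.  Moments are population
moments (kurtosis is not excess-corrected).
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]


def first_order_features(values, voxel_volume_mm3, discretized):
    """All 18 first-order features of a voxel intensity sample.

    Parameters
    ----------
    values : 1D array of raw intensities inside the region
    voxel_volume_mm3 : physical volume of one voxel
    discretized : 1D int array, same voxels binned at fixed bin width
    """
    x = np.asarray(values, float)
    n = x.size
    counts = np.bincount(discretized)[1:]
    p = counts[counts > 0] / n
    mean = x.mean()
    var = x.var()
    centered = x - mean
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        skew = np.mean(centered**3) / m2**1.5
        kurt = np.mean(centered**4) / m2**2
    else:
        skew, kurt = 0.0, 0.0
    return dict(
        zip(
            FIRST_ORDER_NAMES,
            [
                float(np.sum(x**2)),
                float(voxel_volume_mm3 * np.sum(x**2)),
                float(-(p * np.log2(p)).sum()),
                float(x.min()),
                float(p10),
                float(p90),
                float(x.max()),
                float(mean),
                float(p50),
                float(p75 - p25),
                float(x.max() - x.min()),
                float(np.abs(centered).mean()),
                float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
                float(np.sqrt(np.mean(x**2))),
                float(skew),
                float(kurt),
                float(var),
                float((p**2).sum()),
            ],
        )
    )
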