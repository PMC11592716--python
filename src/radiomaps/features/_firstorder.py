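"""First-order (intensity-histogram) features of a patch.

18 features. Entropy and Uniformity are computed on the discretized
histogram; everything else on the raw intensities. Conventions:

* population (biased) variance;
* skewness in population form, defined as 0 for a constant patch;
* kurtosis uncorrected (Pearson form; a normal sample gives ~3), 0 for a
  constant patch;
* Energy uses no intensity shift (c = 0); TotalEnergy = Energy x voxel
  volume in mm^3;
* log base 2 with 0*log(0) = 0.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]


def level_probabilities(levels: np.ndarray) -> np.ndarray:
    counts = np.bincount(levels.ravel())[1:]  # levels start at 1
    counts = counts[counts > 0]
    return counts / counts.sum()


def firstorder_features(
    intensities: np.ndarray,
    levels: np.ndarray,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty patch")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    energy = float(np.sum(x**2))
    p = level_probabilities(np.asarray(levels))
    entropy = float(-np.sum(p * np.log2(p)))
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "TotalEnergy": energy * float(voxel_volume),
        "Uniformity": float(np.sum(p**2)),
        "Variance": float(m2),
    }
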