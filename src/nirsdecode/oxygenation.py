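"""Per-channel oxygenation features on an 80-sample kept window.

Seven scalars per (channel, chromophore, epoch): peak (signed maximum), mean,
variance, skewness, kurtosis, area under the curve (sum of absolute values),
and the least-squares linear slope against time in seconds. Moments use the
population (1/N) convention inside the moment ratios and kurtosis is
non-excess (a Gaussian scores 3). Skewness and kurtosis are undefined on a
zero-variance window and are returned as NaN; downstream feature assembly
drops such dimensions with a warning rather than dropping the epoch.
"""

from __future__ import annotations

import warnings

import numpy as np

OXYGENATION_FEATURES = (
    "peak", "average", "variance", "skewness", "kurtosis", "auc", "slope",
)


def oxygenation_features(x: np.ndarray, fs: float = 7.8125) -> dict[str, np.ndarray]:
    """Compute the seven features along the last axis of ``x``.

    Returns a dict feature name -> array of the leading shape of ``x``.
    The slope's time axis is ``arange(n) / fs`` seconds, so its units are
    concentration per second regardless of sampling rate.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    mean = x.mean(axis=-1)
    dev = x - mean[..., None]
    m2 = np.mean(dev ** 2, axis=-1)
    m3 = np.mean(dev ** 3, axis=-1)
    m4 = np.mean(dev ** 4, axis=-1)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / safe_m2 ** 1.5, np.nan)
    kurt = np.where(m2 > 0, m4 / safe_m2 ** 2, np.nan)
    if np.any(m2 == 0):
        warnings.warn("zero-variance window: skewness/kurtosis undefined (NaN)",
                      RuntimeWarning, stacklevel=2)
    t = np.arange(n) / fs
    t_dev = t - t.mean()
    slope = (dev * t_dev).sum(axis=-1) / (t_dev ** 2).sum()
    return {
        "peak": x.max(axis=-1),
        "average": mean,
        "variance": m2,
        "skewness": skew,
        "kurtosis": kurt,
        "auc": np.abs(x).sum(axis=-1),
        "slope": slope,
    }
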