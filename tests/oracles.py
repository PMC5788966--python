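"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit sums / DFT matrices and stays
independent of the package's vectorized/FFT code paths.
"""

from __future__ import annotations

import numpy as np


# -- moment features (explicit loops) ---------------------------------------

def slow_oxygenation(x, fs):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    t = [i / fs for i in range(n)]
    tbar = sum(t) / n
    slope = sum((ti - tbar) * (v - mean) for ti, v in zip(t, x)) \
        / sum((ti - tbar) ** 2 for ti in t)
    return {
        "peak": max(x),
        "average": mean,
        "variance": m2,
        "skewness": m3 / m2 ** 1.5 if m2 > 0 else float("nan"),
        "kurtosis": m4 / m2 ** 2 if m2 > 0 else float("nan"),
        "auc": sum(abs(v) for v in x),
        "slope": slope,
    }


# -- time-domain connectivity (explicit sums) -------------------------------

def slow_covariance(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)


def slow_pearson(x, y):
    sx = np.sqrt(slow_covariance(x, x))
    sy = np.sqrt(slow_covariance(y, y))
    return slow_covariance(x, y) / (sx * sy)


def average_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def slow_spearman(x, y):
    return slow_pearson(average_ranks(list(x)), average_ranks(list(y)))


# -- Welch coherence via explicit DFT ---------------------------------------

def dft_matrix(n):
    j, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.exp(-2j * np.pi * j * k / n)


def slow_welch_coherence(x, y, fs, nperseg, noverlap, window):
    """Eq. 7 with segment spectra computed by an explicit DFT matrix."""
    from scipy.signal import get_window
    step = nperseg - noverlap
    k = (len(x) - noverlap) // step
    win = get_window(window, nperseg)
    E = dft_matrix(nperseg)
    gxx = gyy = gxy = 0.0
    for i in range(k):
        sx = np.asarray(x[i * step:i * step + nperseg], dtype=float)
        sy = np.asarray(y[i * step:i * step + nperseg], dtype=float)
        sx = (sx - sx.mean()) * win
        sy = (sy - sy.mean()) * win
        X = E @ sx
        Y = E @ sy
        gxx = gxx + np.abs(X) ** 2
        gyy = gyy + np.abs(Y) ** 2
        gxy = gxy + X * np.conj(Y)
    cxy = np.abs(gxy) ** 2 / (gxx * gyy)
    f = np.arange(nperseg) * fs / nperseg
    half = nperseg // 2 + 1
    return f[:half], cxy[:half]


# -- wavelet coherence via explicit DFT matrices ----------------------------

def _pow2(n):
    return 1 << int(n - 1).bit_length()


def slow_morlet_cwt(x, dt, scales, omega0):
    """Morlet CWT evaluated with explicit DFT matrices (no FFT)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nf = _pow2(n)
    xp = np.concatenate([x - x.mean(), np.zeros(nf - n)])
    E = dft_matrix(nf)
    Einv = np.conj(E) / nf
    xh = E @ xp
    freqs = np.concatenate([np.arange(nf // 2 + 1), np.arange(-(nf // 2) + 1, 0)])
    omega = 2 * np.pi * freqs / (nf * dt)
    W = np.empty((len(scales), n), dtype=complex)
    for si, s in enumerate(scales):
        psi = (np.pi ** -0.25) * np.sqrt(2 * np.pi * s / dt) \
            * np.exp(-0.5 * (s * omega - omega0) ** 2) * (omega > 0)
        W[si] = (Einv @ (xh * psi))[:n]
    return W


def slow_smooth(z, scales, dt, dj, decorrelation):
    """Gaussian time smoothing + boxcar scale smoothing, explicit DFT/loops."""
    z = np.asarray(z)
    n_s, n = z.shape
    nf = _pow2(2 * n)
    E = dft_matrix(nf)
    Einv = np.conj(E) / nf
    freqs = np.concatenate([np.arange(nf // 2 + 1), np.arange(-(nf // 2) + 1, 0)])
    omega = 2 * np.pi * freqs / (nf * dt)
    out = np.empty_like(z, dtype=complex)
    for si, s in enumerate(scales):
        h = np.exp(-0.5 * (s * omega) ** 2)
        zp = np.concatenate([z[si], np.zeros(nf - n)])
        out[si] = (Einv @ ((E @ zp) * h))[:n]
    # boxcar over scales, edge-renormalised
    win = max(1, int(round(decorrelation / dj)))
    sm = np.empty_like(out)
    for si in range(n_s):
        lo = max(0, si - win // 2)
        hi = min(n_s, si + (win - 1) // 2 + 1)
        sm[si] = out[lo:hi].sum(axis=0) / (hi - lo)
    if not np.iscomplexobj(z):
        return sm.real
    return sm


def slow_wavelet_coherence(x, y, fs, spec):
    """Eq. 8 assembled from the explicit-DFT pieces above."""
    dt = 1.0 / fs
    scales = spec.scales(dt)
    Wx = slow_morlet_cwt(x, dt, scales, spec.omega0)
    Wy = slow_morlet_cwt(y, dt, scales, spec.omega0)
    inv_s = 1.0 / scales[:, None]
    sxx = slow_smooth(np.abs(Wx) ** 2 * inv_s, scales, dt, spec.dj,
                      spec.scale_decorrelation)
    syy = slow_smooth(np.abs(Wy) ** 2 * inv_s, scales, dt, spec.dj,
                      spec.scale_decorrelation)
    sxy = slow_smooth(Wx * np.conj(Wy) * inv_s, scales, dt, spec.dj,
                      spec.scale_decorrelation)
    return np.abs(sxy) ** 2 / (sxx.real * syy.real)


# -- exact binomial tail by pmf summation -----------------------------------

def slow_chance_threshold(n, c, alpha):
    from math import comb
    p = 1.0 / c
    cdf = 0.0
    for k in range(n + 1):
        cdf += comb(n, k) * p ** k * (1 - p) ** (n - k)
        if cdf >= 1 - alpha - 1e-12:
            return 100.0 * k / n
    return 100.0
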