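"""Vectorized all-pairs feature extraction over whole sessions.

These helpers compute, for a stack of epochs, the same quantities as the
scalar functions in :mod:`nirsdecode.connectivity` but batched over channels
and channel pairs; tests assert exact agreement with the per-pair reference
path. Time-domain measures operate on the 80-sample kept windows; the two
coherence measures operate on the full 200-sample epochs and are band-averaged
over the central window.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .connectivity import BandSpec, MorletSpec, WelchSpec, morlet_cwt, \
    smooth_operator
from .preprocessing import WINDOW_SLICE

CONNECTIVITY_MEASURES = (
    "covariance", "pearson", "spearman", "coherence", "wavelet_coherence",
)


def pair_indices(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index arrays (ia, ib) in canonical pair order."""
    ia, ib = np.triu_indices(n_channels, k=1)
    return ia, ib


def _corr_matrices(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariance (N-1) and Pearson matrices for (E, C, T) windows."""
    dev = windows - windows.mean(axis=-1, keepdims=True)
    n = windows.shape[-1]
    cov = np.einsum("ecr,edr->ecd", dev, dev) / (n - 1)
    sd = np.sqrt(np.einsum("ecc->ec", cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd[:, :, None] * sd[:, None, :])
    return cov, corr


def time_domain_pair_features(windows: np.ndarray) -> dict[str, np.ndarray]:
    """Covariance, Pearson and Spearman for every pair; (E, n_pairs) each."""
    windows = np.asarray(windows, dtype=float)
    e, c, _ = windows.shape
    ia, ib = pair_indices(c)
    cov, corr = _corr_matrices(windows)
    ranks = sp_stats.rankdata(windows, axis=-1)
    _, rank_corr = _corr_matrices(ranks)
    return {
        "covariance": cov[:, ia, ib],
        "pearson": corr[:, ia, ib],
        "spearman": rank_corr[:, ia, ib],
    }


def welch_band_coherence(epochs: np.ndarray, fs: float,
                         spec: WelchSpec | None = None,
                         band: BandSpec | None = None) -> np.ndarray:
    """Band-averaged Welch magnitude-squared coherence, (E, n_pairs).

    Identical estimator to :func:`nirsdecode.connectivity.spectral_coherence`
    (Hamming taper, constant detrend per segment, K averaged segments).
    """
    spec = spec if spec is not None else WelchSpec()
    band = band if band is not None else BandSpec()
    epochs = np.asarray(epochs, dtype=float)
    e, c, n = epochs.shape
    k = spec.n_segments(n)
    if k < 2:
        raise ValueError(f"{n} samples give {k} Welch segment(s); need >= 2")
    step = spec.nperseg - spec.noverlap
    win = sp_signal.get_window(spec.window, spec.nperseg)
    segs = np.stack([epochs[..., i * step:i * step + spec.nperseg]
                     for i in range(k)], axis=2)        # (E, C, K, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)     # constant detrend
    X = np.fft.rfft(segs * win, axis=-1)                # (E, C, K, F)
    f = np.fft.rfftfreq(spec.nperseg, d=1.0 / fs)
    mask = (f >= band.low_hz) & (f <= band.high_hz)
    if not mask.any():
        raise ValueError("band selects no Welch frequency bin")
    Xb = X[..., mask]                                   # (E, C, K, Fb)
    pxx = np.sum(np.abs(Xb) ** 2, axis=2)               # (E, C, Fb)
    ia, ib = pair_indices(c)
    pxy = np.sum(Xb[:, ia] * np.conj(Xb[:, ib]), axis=2)  # (E, P, Fb)
    cxy = np.abs(pxy) ** 2 / (pxx[:, ia] * pxx[:, ib])
    return cxy.mean(axis=-1)


def wavelet_band_coherence(epochs: np.ndarray, fs: float,
                           spec: MorletSpec | None = None,
                           band: BandSpec | None = None,
                           crop: slice | None = WINDOW_SLICE,
                           chunk: int = 128,
                           precision: str = "double") -> np.ndarray:
    """Band-averaged wavelet coherence for every channel pair, (E, n_pairs).

    Computes channel CWTs once per epoch and forms cross spectra per pair in
    chunks. The scale grid is restricted to the analysis band plus the scale-
    smoothing half-width, which leaves the band-interior values bit-identical
    to a full-grid computation. ``precision="single"`` runs the transforms in
    float32/complex64 (band averages agree with the double-precision path to
    ~1e-6, ample for classification features).
    """
    spec = spec if spec is not None else MorletSpec()
    band = band if band is not None else BandSpec()
    if precision not in ("single", "double"):
        raise ValueError("precision must be 'single' or 'double'")
    work = np.float32 if precision == "single" else np.float64
    epochs = np.asarray(epochs, dtype=work)
    e, c, n = epochs.shape
    dt = 1.0 / fs
    scales_full = spec.scales(dt)
    freqs = 1.0 / (spec.fourier_factor * scales_full)
    in_band = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not in_band.any():
        raise ValueError("band selects no wavelet scale")
    idx = np.flatnonzero(in_band)
    half = max(1, int(round(spec.scale_decorrelation / spec.dj))) // 2
    lo = max(0, idx[0] - half)
    hi = min(len(scales_full), idx[-1] + half + 1)
    scales = scales_full[lo:hi]
    band_rows = idx - lo

    ia, ib = pair_indices(c)
    out = np.empty((e, len(ia)))
    inv_s = (1.0 / scales[:, None]).astype(work)
    t_sel = crop if crop is not None else slice(None)
    for ei in range(e):
        W = morlet_cwt(epochs[ei], dt, scales, spec.omega0)   # (C, S, n)
        P = smooth_operator(np.abs(W) ** 2 * inv_s, scales, dt, spec)
        Pb = P[:, band_rows][..., t_sel]                      # (C, Sb, Tc)
        for start in range(0, len(ia), chunk):
            sl = slice(start, start + chunk)
            Wxy = W[ia[sl]] * np.conj(W[ib[sl]]) * inv_s
            Sxy = smooth_operator(Wxy, scales, dt, spec)
            num = np.abs(Sxy[:, band_rows][..., t_sel]) ** 2
            denom = Pb[ia[sl]] * Pb[ib[sl]]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, num / denom, 0.0)
            out[ei, sl] = np.clip(r2, 0.0, 1.0).mean(axis=(1, 2))
    return out
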