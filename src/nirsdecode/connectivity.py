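"""Pairwise connectivity measures between channel signals.

Five measures per channel pair and chromophore: covariance, Pearson and
Spearman correlation (time domain, computed on the 80-sample kept window),
Welch magnitude-squared coherence and Morlet wavelet coherence (time-frequency
domain, computed on the full 200-sample epoch and cropped to the central
window before band averaging).

The wavelet coherence follows the Torrence-Compo continuous-wavelet
construction: a Morlet mother wavelet (omega0 = 6 by default) on a
dyadic-fractional scale grid s_j = s0 * 2**(j*dj), cross-wavelet spectrum
W_xy = W_x * conj(W_y), and squared coherence

    R2(s, n) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where S smooths in time with a Gaussian whose width tracks the scale and in
scale with a boxcar over the Morlet decorrelation length (0.6 / dj scale
steps). Without smoothing the expression is identically 1 for any pair, which
is why S is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal, stats


# ---------------------------------------------------------------------------
# time-domain measures

def covariance(x: np.ndarray, y: np.ndarray, ddof: int = 1) -> float:
    """Sample covariance (divisor N - ddof, default N-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.cov(x, y, ddof=ddof)[0, 1])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (flagged missing) on a zero-variance signal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson on average ranks); NaN if all-tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Welch magnitude-squared coherence

@dataclass(frozen=True)
class WelchSpec:
    """Welch estimator parameters for the spectral coherence.

    Defaults resolve the 0.078-0.3125 Hz analysis band on a 200-sample epoch
    with K = 3 averaged segments (K = 1 would make the estimate identically 1).
    """

    nperseg: int = 100
    noverlap: int = 50
    window: str = "hamming"
    detrend: str = "constant"

    def n_segments(self, n_samples: int) -> int:
        if n_samples < self.nperseg:
            return 0
        return (n_samples - self.noverlap) // (self.nperseg - self.noverlap)


@dataclass
class CoherenceSpectrum:
    f: np.ndarray
    cxy: np.ndarray
    spec: WelchSpec
    n_segments: int


def spectral_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                       spec: WelchSpec | None = None) -> CoherenceSpectrum:
    """Magnitude-squared coherence |Gxy|^2 / (Gxx * Gyy) via Welch averaging.

    Requires at least two segments: with a single segment the estimator is
    algebraically identical to 1 at every frequency and carries no
    information.
    """
    spec = spec if spec is not None else WelchSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    k = spec.n_segments(x.shape[-1])
    if k < 2:
        raise ValueError(
            f"{x.shape[-1]} samples give {k} Welch segment(s); need >= 2 "
            "(a single-segment coherence estimate is identically 1)")
    f, cxy = signal.coherence(x, y, fs=fs, window=spec.window,
                              nperseg=spec.nperseg, noverlap=spec.noverlap,
                              detrend=spec.detrend)
    return CoherenceSpectrum(f=f, cxy=cxy, spec=spec, n_segments=k)


# ---------------------------------------------------------------------------
# Morlet wavelet coherence (Torrence-Compo construction)

@dataclass(frozen=True)
class MorletSpec:
    """Morlet CWT grid: scales s_j = s0 * 2**(j*dj) with period <= max_period.

    omega0 = 6 makes the equivalent Fourier period ~1.033 x scale. ``s0``
    defaults to 2*dt. ``scale_decorrelation`` is the Morlet decorrelation
    length in octaves governing the boxcar scale smoothing (0.6).
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s0: float | None = None
    max_period: float = 12.8
    scale_decorrelation: float = 0.6

    @property
    def fourier_factor(self) -> float:
        w0 = self.omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 * w0))

    def scales(self, dt: float) -> np.ndarray:
        s0 = 2.0 * dt if self.s0 is None else self.s0
        smax = self.max_period / self.fourier_factor
        if smax < s0:
            raise ValueError("max_period smaller than the smallest scale period")
        j_max = int(np.floor(np.log2(smax / s0) / self.dj))
        return s0 * 2.0 ** (self.dj * np.arange(j_max + 1))


@dataclass
class WaveletCoherenceMap:
    """Squared wavelet coherence R2(scale, time) for one channel pair."""

    scales: np.ndarray        # (S,) in seconds
    periods: np.ndarray       # (S,) fourier_factor * scales
    times: np.ndarray         # (T,) sample indices into the source epoch
    r2: np.ndarray            # (S, T) in [0, 1]
    coi_period: np.ndarray    # (T,) cone-of-influence period at each time
    spec: MorletSpec
    smoothed: bool = True

    @property
    def frequencies(self) -> np.ndarray:
        return 1.0 / self.periods


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def morlet_cwt(x: np.ndarray, dt: float, scales: np.ndarray,
               omega0: float = 6.0, n_fft: int | None = None) -> np.ndarray:
    """Continuous Morlet wavelet transform, shape (n_scales, len(x)).

    FFT implementation with zero padding to the next power of two; the
    energy normalisation sqrt(2*pi*s/dt) keeps white-noise variance flat
    across scales.
    """
    x = np.asarray(x)
    if x.dtype != np.float32:
        x = x.astype(np.float64)
    real_dtype = x.dtype
    n = x.shape[-1]
    nf = _next_pow2(n) if n_fft is None else n_fft
    xh = sp_fft.fft(x - x.mean(axis=-1, keepdims=True), nf, axis=-1)
    # angular frequency grid with k <= N/2 counted positive (the Nyquist bin
    # contributes to the smallest scales, where s*omega_nyq ~ omega0)
    k = np.concatenate([np.arange(nf // 2 + 1), np.arange(-(nf // 2) + 1, 0)])
    omega = 2.0 * np.pi * k / (nf * dt)
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    arg = scales[:, None] * omega[None, :]
    psi_hat = ((np.pi ** -0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
               * np.exp(-0.5 * (arg - omega0) ** 2) * (omega[None, :] > 0))
    W = sp_fft.ifft(xh[..., None, :] * psi_hat.astype(real_dtype), axis=-1)
    return W[..., :n]


def _smooth_time(z: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Scale-dependent Gaussian time smoothing along the last axis.

    Implemented in the frequency domain: the transfer function of the
    normalized Gaussian kernel exp(-t^2/(2 s^2)) is exp(-s^2 w^2 / 2).
    Accepts real or complex ``z`` of shape (..., S, T).
    """
    n = z.shape[-1]
    nf = _next_pow2(2 * n)  # pad so circular wrap-around is negligible
    omega = 2.0 * np.pi * np.fft.fftfreq(nf, d=dt)
    h = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    if z.dtype in (np.float32, np.complex64):
        h = h.astype(np.float32)
    zh = sp_fft.fft(z, nf, axis=-1)
    sm = sp_fft.ifft(zh * h, axis=-1)[..., :n]
    return sm if np.iscomplexobj(z) else sm.real


def _boxcar_same(a: np.ndarray, win: int, axis: int) -> np.ndarray:
    """Centered running sum of width ``win`` along ``axis`` (edges clipped)."""
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    csum = np.concatenate([np.zeros_like(a[:1]), np.cumsum(a, axis=0)], axis=0)
    i = np.arange(n)
    left = np.clip(i - win // 2, 0, n)
    right = np.clip(i + (win - 1) // 2 + 1, 0, n)
    return np.moveaxis(csum[right] - csum[left], 0, axis)


def _smooth_scale(z: np.ndarray, dj: float, decorrelation: float) -> np.ndarray:
    """Boxcar smoothing over the scale axis (axis -2), edge-renormalised."""
    win = max(1, int(round(decorrelation / dj)))
    if win == 1:
        return z
    n_s = z.shape[-2]
    counts = _boxcar_same(np.ones(n_s), win, 0).reshape((-1, 1))
    return _boxcar_same(z, win, -2) / counts


def smooth_operator(z: np.ndarray, scales: np.ndarray, dt: float,
                    spec: MorletSpec) -> np.ndarray:
    """The combined smoothing S: Gaussian in time, boxcar in scale."""
    return _smooth_scale(_smooth_time(z, scales, dt), spec.dj,
                         spec.scale_decorrelation)


def _coi_period(n: int, dt: float, spec: MorletSpec) -> np.ndarray:
    # e-folding time of the Morlet envelope is sqrt(2)*s; a point n samples
    # from the nearest edge is unaffected for periods below ff*n*dt/sqrt(2)
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    return spec.fourier_factor * edge * dt / np.sqrt(2.0)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                      spec: MorletSpec | None = None, smoothing: bool = True,
                      crop: slice | None = None) -> WaveletCoherenceMap:
    """Squared wavelet coherence map of two equal-length signals.

    ``crop`` optionally restricts the returned map to a time slice (the
    pipeline passes the epoch's central-80-sample slice so wavelet edge
    effects stay out of downstream averages). ``smoothing=False`` is exposed
    only to demonstrate that the unsmoothed expression is identically 1.
    """
    spec = spec if spec is not None else MorletSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    n = x.shape[-1]
    if n < 64:
        raise ValueError("need at least 64 samples for a stable coherence map")
    dt = 1.0 / fs
    scales = spec.scales(dt)
    Wx = morlet_cwt(x, dt, scales, spec.omega0)
    Wy = morlet_cwt(y, dt, scales, spec.omega0)
    Wxy = Wx * np.conj(Wy)
    inv_s = 1.0 / scales[:, None]
    if smoothing:
        sxx = smooth_operator(np.abs(Wx) ** 2 * inv_s, scales, dt, spec)
        syy = smooth_operator(np.abs(Wy) ** 2 * inv_s, scales, dt, spec)
        sxy = smooth_operator(Wxy * inv_s, scales, dt, spec)
    else:
        sxx = np.abs(Wx) ** 2 * inv_s
        syy = np.abs(Wy) ** 2 * inv_s
        sxy = Wxy * inv_s
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    times = np.arange(n)
    coi = _coi_period(n, dt, spec)
    if crop is not None:
        r2 = r2[:, crop]
        times = times[crop]
        coi = coi[crop]
    return WaveletCoherenceMap(scales=scales,
                               periods=spec.fourier_factor * scales,
                               times=times, r2=r2, coi_period=coi, spec=spec,
                               smoothed=smoothing)


# ---------------------------------------------------------------------------
# band averaging

@dataclass(frozen=True)
class BandSpec:
    """Closed frequency band for coherence averaging (defaults: 1/12.8 to
    1/3.2 s periods, the low-frequency-oscillation band)."""

    low_hz: float = 1.0 / 12.8
    high_hz: float = 1.0 / 3.2

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low < high")


def band_average(obj: WaveletCoherenceMap | CoherenceSpectrum,
                 band: BandSpec | None = None,
                 time_slice: slice | None = None,
                 exclude_coi: bool = False) -> float:
    """Unweighted mean coherence over all grid points inside the closed band.

    For a wavelet map the average runs over (scale, time) points, optionally
    restricted to a time slice and/or to points outside the cone of
    influence; for a Welch spectrum it runs over frequency bins.
    """
    band = band if band is not None else BandSpec()
    if isinstance(obj, CoherenceSpectrum):
        mask = (obj.f >= band.low_hz) & (obj.f <= band.high_hz)
        if not mask.any():
            raise ValueError(
                f"band [{band.low_hz}, {band.high_hz}] Hz contains no frequency "
                f"bin of the grid {obj.f}")
        return float(obj.cxy[mask].mean())
    freqs = obj.frequencies
    smask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not smask.any():
        raise ValueError(
            f"band [{band.low_hz}, {band.high_hz}] Hz selects no scale; grid "
            f"periods span [{obj.periods[0]:.3f}, {obj.periods[-1]:.3f}] s")
    r2 = obj.r2[smask]
    coi = obj.coi_period
    if time_slice is not None:
        r2 = r2[:, time_slice]
        coi = coi[time_slice]
    if exclude_coi:
        valid = obj.periods[smask][:, None] <= coi[None, :]
        if not valid.any():
            raise ValueError("cone of influence excludes the whole band")
        return float(r2[valid].mean())
    return float(r2.mean())


def all_pairs(channel_ids: list[str]) -> list[tuple[str, str]]:
    """Canonical unordered channel pairs: C(n, 2), lower index first."""
    if len(channel_ids) < 2:
        raise ValueError("need at least 2 channels")
    return [(channel_ids[i], channel_ids[j])
            for i in range(len(channel_ids))
            for j in range(i + 1, len(channel_ids))]
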