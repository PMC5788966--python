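"""Raw intensity -> artifact-corrected, band-passed HbO/HbR epochs.

Each landing is cut into 200-sample epochs whose onsets are 60 samples apart;
every epoch is then processed independently (so the method extends to online
use): intensity -> optical density (reference = per-epoch mean), wavelet-based
motion-artifact correction, Butterworth band-pass (high-pass 0.01 Hz order 3,
low-pass 0.5 Hz order 5), MBLL inversion to HbO/HbR, and finally the central
80 samples are kept for time-domain feature extraction. Time-frequency
transforms operate on the full 200-sample epoch and are cropped to the same
central window afterwards, which keeps wavelet edge effects out of the
analysed region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .mbll import MBLLParams, od_to_hemoglobin
from .synth import RawSession

EPOCH_LEN = 200
EPOCH_STEP = 60
WINDOW_SLICE = slice(60, 140)  # central 80 samples of a 200-sample epoch


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass as a high-pass + low-pass Butterworth cascade."""

    highpass_hz: float = 0.01
    highpass_order: int = 3
    lowpass_hz: float = 0.5
    lowpass_order: int = 5
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.highpass_hz < self.lowpass_hz < nyq):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_hz}) < lowpass "
                f"({self.lowpass_hz}) < Nyquist ({nyq})"
            )


@dataclass
class Epoch:
    """200-sample preprocessed segment, both chromophores, all channels."""

    hbo: np.ndarray          # (C, 200) molar concentration change
    hbr: np.ndarray          # (C, 200)
    landing: int
    condition: str
    index: int
    onset: int               # sample offset within the landing

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO/HbR shape mismatch")
        if self.hbo.shape[-1] != EPOCH_LEN:
            raise ValueError(f"epoch must have {EPOCH_LEN} samples")


@dataclass
class KeptWindow:
    """Central 80 samples of an epoch — the unit of time-domain features."""

    hbo: np.ndarray          # (C, 80)
    hbr: np.ndarray
    landing: int
    condition: str
    index: int


def intensity_to_od(intensity: np.ndarray, reference: np.ndarray | None = None,
                    channel_ids: list[str] | None = None) -> np.ndarray:
    """Optical density OD(t) = -log10(I(t) / I_ref) along the last axis.

    ``reference`` defaults to the per-series mean over time. Raises on any
    non-positive sample, naming the offending channel and sample.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        idx = np.argwhere(intensity <= 0)[0]
        name = (channel_ids[idx[-2]] if channel_ids is not None
                and intensity.ndim >= 2 else str(tuple(idx[:-1])))
        raise ValueError(
            f"non-positive intensity at channel {name}, sample {idx[-1]}")
    if reference is None:
        reference = intensity.mean(axis=-1, keepdims=True)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("non-positive reference intensity")
    return -np.log10(intensity / reference)


def wavelet_artifact_correct(od: np.ndarray, iqr_factor: float = 1.5,
                             wavelet: str = "db2",
                             level: int | None = None,
                             min_coefficients: int = 8,
                             mode: str = "antireflect") -> np.ndarray:
    """Suppress motion artifacts by zeroing outlier wavelet detail coefficients.

    The series (last axis) is decomposed with a discrete wavelet transform
    (db2, maximal dyadic depth by default); within each detail level,
    coefficients outside [q1 - f*IQR, q3 + f*IQR] are set to zero and the
    signal is reconstructed. Smooth physiological content passes through
    nearly unchanged while transient spikes concentrate in few large
    coefficients and are removed.

    Two guards adapt the interquartile rule to short (200-sample) epochs:
    the signal is extended by ``antireflect`` (slope-preserving) padding so a
    smooth epoch produces no spurious edge coefficients, and levels holding
    fewer than ``min_coefficients`` coefficients pass through untouched —
    quartiles estimated from a handful of values are meaningless and would
    clip genuine low-frequency signal.
    """
    od = np.asarray(od, dtype=float)
    n = od.shape[-1]
    max_level = pywt.dwt_max_level(n, wavelet)
    if level is None:
        level = max_level
    if level < 1 or level > max_level:
        raise ValueError(f"epoch of {n} samples supports levels 1..{max_level}")

    def _one(x: np.ndarray) -> np.ndarray:
        coeffs = pywt.wavedec(x, wavelet, level=level, mode=mode)
        out = [coeffs[0]]
        for det in coeffs[1:]:
            if len(det) >= min_coefficients:
                q1, q3 = np.percentile(det, [25, 75])
                iqr = q3 - q1
                lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
                det = np.where((det < lo) | (det > hi), 0.0, det)
            out.append(det)
        return pywt.waverec(out, wavelet, mode=mode)[:n]

    return np.apply_along_axis(_one, -1, od)


def bandpass(od: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Butterworth high-pass then low-pass along the last axis.

    Zero-phase mode applies each filter forward-backward (no group delay);
    causal mode applies them once for online-compatible processing.
    """
    spec.validate(fs)
    hp = signal.butter(spec.highpass_order, spec.highpass_hz,
                       btype="highpass", fs=fs, output="sos")
    lp = signal.butter(spec.lowpass_order, spec.lowpass_hz,
                       btype="lowpass", fs=fs, output="sos")
    if spec.zero_phase:
        x = signal.sosfiltfilt(hp, od, axis=-1)
        return signal.sosfiltfilt(lp, x, axis=-1)
    x = signal.sosfilt(hp, od, axis=-1)
    return signal.sosfilt(lp, x, axis=-1)


def segment_bounds(n_samples: int, epoch_len: int = EPOCH_LEN,
                   step: int = EPOCH_STEP) -> list[tuple[int, int]]:
    """Onset/end pairs of the epochs that fit in a landing of ``n_samples``."""
    if n_samples < epoch_len:
        raise ValueError(
            f"landing of {n_samples} samples is shorter than one epoch "
            f"({epoch_len} samples)")
    n_epochs = (n_samples - epoch_len) // step + 1
    return [(i * step, i * step + epoch_len) for i in range(n_epochs)]


def segment_epochs(session: RawSession, mbll: MBLLParams | None = None,
                   filter_spec: FilterSpec | None = None,
                   iqr_factor: float = 1.5,
                   artifact_correction: bool = True,
                   filtering: bool = True,
                   max_epochs_per_landing: int | None = None,
                   epoch_len: int = EPOCH_LEN,
                   step: int = EPOCH_STEP) -> list[Epoch]:
    """Full per-epoch pipeline over a session's landings.

    The number of epochs per landing is the minimum count over the subject's
    landings (so every landing contributes equally), optionally further capped
    by ``max_epochs_per_landing``.
    """
    mbll = mbll if mbll is not None else MBLLParams()
    spec = filter_spec if filter_spec is not None else FilterSpec()
    fs = session.montage.sampling_rate

    per_landing = [segment_bounds(l.intensity.shape[-1], epoch_len, step)
                   for l in session.landings]
    cap = min(len(b) for b in per_landing)
    if max_epochs_per_landing is not None:
        cap = min(cap, max_epochs_per_landing)

    epochs: list[Epoch] = []
    for li, (landing, bounds) in enumerate(zip(session.landings, per_landing)):
        for ei, (a, b) in enumerate(bounds[:cap]):
            raw = landing.intensity[:, :, a:b]          # (2, C, epoch_len)
            od = intensity_to_od(raw, channel_ids=session.montage.channel_ids)
            if artifact_correction:
                od = wavelet_artifact_correct(od, iqr_factor=iqr_factor)
            if filtering:
                od = bandpass(od, spec, fs)
            hbo, hbr = od_to_hemoglobin(od, mbll)
            epochs.append(Epoch(hbo=hbo, hbr=hbr, landing=li,
                                condition=landing.condition, index=ei, onset=a))
    return epochs


def central_window(epoch: Epoch) -> KeptWindow:
    """Samples 60..139 (0-based, half-open [60, 140)) of a 200-sample epoch."""
    if epoch.hbo.shape[-1] != EPOCH_LEN:
        raise ValueError(f"epoch must have {EPOCH_LEN} samples")
    return KeptWindow(hbo=epoch.hbo[..., WINDOW_SLICE].copy(),
                      hbr=epoch.hbr[..., WINDOW_SLICE].copy(),
                      landing=epoch.landing, condition=epoch.condition,
                      index=epoch.index)
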