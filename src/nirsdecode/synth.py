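"""Two-condition synthetic fNIRS session generator.

Emulates the statistical structure the downstream analysis assumes: each
session holds 8 "landings" (4 per condition, pseudo-randomly ordered) of
42-channel two-wavelength intensity recordings. Hemodynamics are built as a
ROI-latent mixture:

* one band-limited low-frequency-oscillation (LFO, ~0.06-0.12 Hz) latent per
  ROI plus a pink-noise floor; inter-ROI coupling is imposed by mixing
  independent standardized sources through the Cholesky factor of the
  condition's target correlation matrix, so the latent cross-correlations
  reproduce any positive-semidefinite coupling matrix;
* per-channel HbO = LFO amplitude x ROI latent + condition activation offset
  + global nuisances (cardiac, respiration, Mayer wave) + channel noise;
* HbR = anti-correlation gain x (HbO minus its private noise) + HbR noise,
  so with all noise amplitudes at zero corr(HbO, HbR) = -1 per channel;
* both chromophores go through the forward modified Beer-Lambert model into
  optical density; motion artifacts (exponentially decaying spikes and step
  baseline shifts) are injected in OD space; intensities are
  baseline * 10**(-OD).

The two conditions may differ in inter-ROI coupling (drives connectivity
features) and in mean HbO offset (drives oxygenation features); either
contrast can be zeroed independently for null testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .mbll import MBLLParams, hemoglobin_to_od
from .montage import Montage, build_default_montage

CONDITIONS = ("manual", "auto")


def uniform_coupling(n_roi: int, rho: float) -> np.ndarray:
    """Symmetric coupling matrix with unit diagonal and constant off-diagonal."""
    m = np.full((n_roi, n_roi), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class GeneratorConfig:
    """All knobs of the session generator.

    Concentration amplitudes are molar (1e-6 = 1 uM). Defaults express the
    study conditions: a strongly coupled, activated "manual" (high-engagement)
    condition against a weakly coupled "auto" condition.
    """

    n_subjects: int = 1
    landings_per_condition: int = 4
    duration_mean_s: float = 152.0
    duration_sd_s: float = 22.0
    duration_floor_s: float = 120.0
    # condition -> 6x6 (or R x R) symmetric coupling matrix
    coupling: dict[str, np.ndarray] | None = None
    # condition -> mean HbO activation offset (M)
    activation_offset: dict[str, float] | None = None
    lfo_band: tuple[float, float] = (0.06, 0.12)
    lfo_amplitude: float = 0.3e-6
    lfo_fraction: float = 0.8          # latent variance fraction in the LFO band
    cardiac_freq: float = 1.1
    cardiac_amplitude: float = 0.05e-6
    resp_freq: float = 0.25
    resp_amplitude: float = 0.1e-6
    mayer_freq: float = 0.1
    mayer_amplitude: float = 0.1e-6
    channel_noise_sd: float = 0.1e-6
    hbr_gain: float = -0.5
    hbr_noise_sd: float = 0.05e-6
    artifact_rate_per_min: float = 1.0
    artifact_amplitude_range: tuple[float, float] = (0.02, 0.08)  # OD units
    artifact_decay_s: float = 0.5
    shift_rate_per_min: float = 0.2
    shift_amplitude_range: tuple[float, float] = (0.005, 0.02)    # OD units
    baseline_intensity: float = 1.0
    mbll: MBLLParams = field(default_factory=MBLLParams)
    keep_internals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = {
                "manual": uniform_coupling(6, 0.75),
                "auto": uniform_coupling(6, 0.25),
            }
        if self.activation_offset is None:
            self.activation_offset = {"manual": 0.3e-6, "auto": 0.0}
        if self.baseline_intensity <= 0:
            raise ValueError("baseline intensity must be > 0")
        for name in ("lfo_amplitude", "cardiac_amplitude", "resp_amplitude",
                     "mayer_amplitude", "channel_noise_sd", "hbr_noise_sd",
                     "artifact_rate_per_min", "shift_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cond, m in self.coupling.items():
            m = np.asarray(m, dtype=float)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"coupling matrix for {cond!r} is not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError(f"coupling matrix for {cond!r} lacks unit diagonal")
            self.coupling[cond] = m


@dataclass
class ArtifactEvent:
    time_s: float
    channel_id: str
    amplitude: float
    kind: str  # "spike" | "shift"


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    condition_order: list[str]
    coupling: dict[str, np.ndarray]
    artifacts: list[list[ArtifactEvent]]   # per landing
    seed: int
    # optional internal traces, per landing (keep_internals=True):
    hbo: list[np.ndarray] = field(default_factory=list)   # (C, T) molar
    hbr: list[np.ndarray] = field(default_factory=list)
    od: list[np.ndarray] = field(default_factory=list)    # (2, C, T) incl. artifacts


@dataclass
class Landing:
    condition: str
    intensity: np.ndarray   # (2 wavelengths, C channels, T samples), positive
    duration_s: float


@dataclass
class RawSession:
    montage: Montage
    landings: list[Landing]
    ground_truth: GroundTruth
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        for lnd in self.landings:
            if lnd.intensity.shape[1] != self.montage.n_channels:
                raise ValueError("landing channel count does not match montage")
            if np.any(lnd.intensity <= 0):
                raise ValueError("intensities must be strictly positive")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    pad = int(round(60 * fs))  # discard filter transients
    x = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)[pad:pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    y = np.fft.irfft(spec * scale, n)
    return (y - y.mean()) / y.std()


def _coupling_mixer(coupling: np.ndarray) -> np.ndarray:
    """Cholesky-type mixing matrix L with L @ L.T = coupling (PSD-corrected)."""
    c = np.asarray(coupling, dtype=float)
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(c)
        if w.min() < -1e-8:
            raise ValueError("coupling matrix is not PSD-correctable") from None
        w = np.clip(w, 0.0, None)
        L = v * np.sqrt(w)
        # re-normalise rows so the diagonal of L L^T stays 1
        norms = np.linalg.norm(L, axis=1, keepdims=True)
        return L / np.where(norms > 0, norms, 1.0)


def _landing_durations(rng: np.random.Generator, cfg: GeneratorConfig,
                       n: int) -> np.ndarray:
    a = (cfg.duration_floor_s - cfg.duration_mean_s) / cfg.duration_sd_s
    return stats.truncnorm.rvs(
        a, np.inf, loc=cfg.duration_mean_s, scale=cfg.duration_sd_s,
        size=n, random_state=rng,
    )


def _simulate_landing(rng: np.random.Generator, cfg: GeneratorConfig,
                      montage: Montage, condition: str, duration_s: float):
    fs = montage.sampling_rate
    n = int(round(duration_s * fs))
    n_ch = montage.n_channels
    rois = montage.rois
    roi_index = np.array([rois.index(c.roi) for c in montage.channels])
    n_roi = len(rois)

    coupling = cfg.coupling[condition]
    if coupling.shape != (n_roi, n_roi):
        raise ValueError(
            f"coupling matrix shape {coupling.shape} does not match {n_roi} ROIs"
        )
    L = _coupling_mixer(coupling)

    # independent standardized sources -> coupled ROI latents
    sources = np.empty((n_roi, n))
    for r in range(n_roi):
        lfo = _bandlimited_noise(rng, n, fs, cfg.lfo_band)
        pink = _pink_noise(rng, n)
        sources[r] = (np.sqrt(cfg.lfo_fraction) * lfo
                      + np.sqrt(1.0 - cfg.lfo_fraction) * pink)
    latents = L @ sources

    t = np.arange(n) / fs
    nuisance = np.zeros(n)
    for freq, amp in ((cfg.cardiac_freq, cfg.cardiac_amplitude),
                      (cfg.resp_freq, cfg.resp_amplitude),
                      (cfg.mayer_freq, cfg.mayer_amplitude)):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            nuisance += amp * np.sin(2 * np.pi * freq * t + phase)

    offset = cfg.activation_offset[condition]
    clean = cfg.lfo_amplitude * latents[roi_index] + offset + nuisance
    noise = cfg.channel_noise_sd * rng.standard_normal((n_ch, n))
    hbo = clean + noise
    hbr = cfg.hbr_gain * clean + cfg.hbr_noise_sd * rng.standard_normal((n_ch, n))

    od = hemoglobin_to_od(hbo, hbr, cfg.mbll)  # (2, C, T)

    # motion artifacts in OD space, shared across both wavelengths
    events: list[ArtifactEvent] = []
    art = np.zeros((n_ch, n))
    minutes = duration_s / 60.0
    for kind, rate, amp_range in (
        ("spike", cfg.artifact_rate_per_min, cfg.artifact_amplitude_range),
        ("shift", cfg.shift_rate_per_min, cfg.shift_amplitude_range),
    ):
        n_events = rng.poisson(rate * minutes)
        for _ in range(n_events):
            ch = int(rng.integers(n_ch))
            t0 = int(rng.integers(n))
            amp = rng.uniform(*amp_range) * rng.choice([-1.0, 1.0])
            if kind == "spike":
                k = np.arange(n - t0)
                art[ch, t0:] += amp * np.exp(-k / (cfg.artifact_decay_s * fs))
            else:
                art[ch, t0:] += amp
            events.append(ArtifactEvent(t0 / fs, montage.channel_ids[ch], amp, kind))
    od = od + art[None, :, :]

    intensity = cfg.baseline_intensity * 10.0 ** (-od)
    return intensity, hbo, hbr, od, events


def simulate_session(config: GeneratorConfig, montage: Montage | None = None,
                     subject_id: str = "S01",
                     seed: int | None = None) -> RawSession:
    """Simulate one subject's session: 2 x landings_per_condition landings.

    ``seed`` overrides ``config.seed`` (used for per-subject sub-seeding).
    Identical (config, seed, montage) inputs give bit-identical output.
    """
    if montage is None:
        montage = build_default_montage()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    order = [c for c in CONDITIONS for _ in range(config.landings_per_condition)]
    order = [order[i] for i in rng.permutation(len(order))]
    durations = _landing_durations(rng, config, len(order))

    landings: list[Landing] = []
    gt = GroundTruth(condition_order=list(order),
                     coupling={k: v.copy() for k, v in config.coupling.items()},
                     artifacts=[], seed=seed)
    for cond, dur in zip(order, durations):
        intensity, hbo, hbr, od, events = _simulate_landing(
            rng, config, montage, cond, float(dur))
        landings.append(Landing(condition=cond, intensity=intensity,
                                duration_s=float(dur)))
        gt.artifacts.append(events)
        if config.keep_internals:
            gt.hbo.append(hbo)
            gt.hbr.append(hbr)
            gt.od.append(od)
    return RawSession(montage=montage, landings=landings, ground_truth=gt,
                      subject_id=subject_id)


def null_config(config: GeneratorConfig | None = None) -> GeneratorConfig:
    """Copy of ``config`` with both condition contrasts removed.

    Both conditions share the mean of the two coupling matrices and a zero
    activation offset, so no feature should separate them beyond chance.
    """
    cfg = config if config is not None else GeneratorConfig()
    mean_coupling = (cfg.coupling["manual"] + cfg.coupling["auto"]) / 2.0
    return replace(
        cfg,
        coupling={"manual": mean_coupling.copy(), "auto": mean_coupling.copy()},
        activation_offset={"manual": 0.0, "auto": 0.0},
    )
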