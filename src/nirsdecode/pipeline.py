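"""End-to-end orchestration: simulate -> preprocess -> features -> classify.

A single master seed is fanned out into per-subject sub-seeds (via
``numpy.random.SeedSequence``) so any subject's session can be regenerated in
isolation. All intermediate products are plain arrays/DataFrames; file
outputs are CSV/JSON, with SNIRF only at the raw-data boundary.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CVResult, SignificanceSpec, chance_threshold, evaluate
from .connectivity import BandSpec, MorletSpec, WelchSpec
from .features_batch import (CONNECTIVITY_MEASURES, pair_indices,
                             time_domain_pair_features, welch_band_coherence,
                             wavelet_band_coherence)
from .montage import Montage, build_default_montage
from .oxygenation import OXYGENATION_FEATURES, oxygenation_features
from .preprocessing import (EPOCH_LEN, EPOCH_STEP, WINDOW_SLICE, FilterSpec,
                            segment_epochs)
from .roi import reduce_connectivity, reduce_oxygenation
from .synth import GeneratorConfig, RawSession, simulate_session

CHROMOPHORES = ("HbO", "HbR")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_subjects: int = 5
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    max_epochs_per_landing: int | None = 12
    oxygenation: tuple[str, ...] = OXYGENATION_FEATURES
    connectivity: tuple[str, ...] = CONNECTIVITY_MEASURES
    chromophores: tuple[str, ...] = CHROMOPHORES
    band: BandSpec = field(default_factory=BandSpec)
    welch: WelchSpec = field(default_factory=WelchSpec)
    morlet: MorletSpec = field(default_factory=MorletSpec)
    evaluate_pairs: bool = True
    wavelet_precision: str = "single"
    shrinkage: float | None = None
    global_zscore: bool = False
    alpha: float = 0.05
    seed: int = 0


def validate_config(cfg: PipelineConfig, montage: Montage | None = None) -> list[str]:
    """Return a list of configuration problems (empty list = valid)."""
    issues: list[str] = []
    mont = montage if montage is not None else build_default_montage()
    fs = mont.sampling_rate
    nyq = fs / 2.0
    if cfg.n_subjects < 1:
        issues.append("n_subjects: must be >= 1")
    if not (0 < cfg.filter_spec.highpass_hz < cfg.filter_spec.lowpass_hz < nyq):
        issues.append("filter_spec: need 0 < highpass < lowpass < Nyquist")
    if cfg.band.high_hz >= nyq:
        issues.append(f"band: upper edge {cfg.band.high_hz} Hz >= Nyquist {nyq} Hz")
    floor_samples = int(cfg.generator.duration_floor_s * fs)
    if floor_samples < EPOCH_LEN:
        issues.append(
            f"generator.duration_floor_s: {cfg.generator.duration_floor_s} s "
            f"({floor_samples} samples) cannot fit one {EPOCH_LEN}-sample epoch")
    elif cfg.max_epochs_per_landing is not None:
        fit = (floor_samples - EPOCH_LEN) // EPOCH_STEP + 1
        if fit < cfg.max_epochs_per_landing:
            issues.append(
                f"generator.duration_floor_s: shortest landing fits only {fit} "
                f"epochs, fewer than max_epochs_per_landing="
                f"{cfg.max_epochs_per_landing}")
    if not 0.0 < cfg.alpha < 1.0:
        issues.append("alpha: must lie in (0, 1)")
    if cfg.wavelet_precision not in ("single", "double"):
        issues.append("wavelet_precision: must be 'single' or 'double'")
    unknown_ox = set(cfg.oxygenation) - set(OXYGENATION_FEATURES)
    if unknown_ox:
        issues.append(f"oxygenation: unknown features {sorted(unknown_ox)}")
    unknown_cn = set(cfg.connectivity) - set(CONNECTIVITY_MEASURES)
    if unknown_cn:
        issues.append(f"connectivity: unknown measures {sorted(unknown_cn)}")
    return issues


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject sub-seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n_subjects) % (2 ** 31)]


@dataclass
class SubjectFeatures:
    """Per-subject feature blocks: chromophore -> feature -> (epochs, dims)."""

    blocks: dict[str, dict[str, np.ndarray]]
    labels: np.ndarray
    landing_ids: np.ndarray
    subject_id: str


def extract_subject_features(session: RawSession,
                             cfg: PipelineConfig) -> SubjectFeatures:
    """Preprocess a session and build ROI-level feature blocks."""
    mont = session.montage
    fs = mont.sampling_rate
    partition = mont.roi_partition()
    epochs = segment_epochs(session, mbll=cfg.generator.mbll,
                            filter_spec=cfg.filter_spec,
                            max_epochs_per_landing=cfg.max_epochs_per_landing)
    labels = np.array([ep.condition for ep in epochs])
    landing_ids = np.array([ep.landing for ep in epochs])
    ia, ib = pair_indices(mont.n_channels)
    pairs = [(mont.channel_ids[i], mont.channel_ids[j]) for i, j in zip(ia, ib)]

    blocks: dict[str, dict[str, np.ndarray]] = {}
    for chrom in cfg.chromophores:
        attr = "hbo" if chrom == "HbO" else "hbr"
        full = np.stack([getattr(ep, attr) for ep in epochs])  # (E, C, 200)
        win = full[..., WINDOW_SLICE]
        feats: dict[str, np.ndarray] = {}
        if cfg.oxygenation:
            ox = oxygenation_features(win, fs=fs)
            for name in cfg.oxygenation:
                feats[name] = reduce_oxygenation(ox[name], mont.channel_ids,
                                                 partition)
        if cfg.connectivity:
            td = time_domain_pair_features(win)
            for name in ("covariance", "pearson", "spearman"):
                if name in cfg.connectivity:
                    feats[name] = reduce_connectivity(td[name], pairs, partition)
            if "coherence" in cfg.connectivity:
                cb = welch_band_coherence(full, fs, cfg.welch, cfg.band)
                feats["coherence"] = reduce_connectivity(cb, pairs, partition)
            if "wavelet_coherence" in cfg.connectivity:
                wb = wavelet_band_coherence(full, fs, cfg.morlet, cfg.band,
                                            crop=WINDOW_SLICE,
                                            precision=cfg.wavelet_precision)
                feats["wavelet_coherence"] = reduce_connectivity(wb, pairs,
                                                                 partition)
        blocks[chrom] = feats
    return SubjectFeatures(blocks=blocks, labels=labels,
                           landing_ids=landing_ids,
                           subject_id=session.subject_id)


@dataclass
class RunReport:
    config: dict
    chance_threshold_pct: float
    results: list[CVResult]
    n_epochs_per_subject: dict[str, int]
    warnings: list[str]
    elapsed_s: float

    def results_frame(self) -> pd.DataFrame:
        rows = [{
            "feature_set": r.feature_set,
            "chromophore": r.chromophore,
            "subject": r.subject_id,
            "mean_accuracy": r.mean_accuracy,
            "n_folds": r.n_folds,
        } for r in self.results]
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        """Rows = feature set, columns = per-subject accuracies + average,
        one table slice per chromophore (long layout)."""
        df = self.results_frame()
        wide = df.pivot_table(index=["feature_set", "chromophore"],
                              columns="subject", values="mean_accuracy")
        wide["average"] = wide.mean(axis=1)
        return wide.reset_index()


def run(cfg: PipelineConfig, montage: Montage | None = None,
        out_dir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline and optionally write CSV/JSON artifacts."""
    t0 = time.time()
    issues = validate_config(cfg, montage)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    mont = montage if montage is not None else build_default_montage()
    seeds = subject_seeds(cfg.seed, cfg.n_subjects)
    results: list[CVResult] = []
    n_epochs: dict[str, int] = {}
    caught: list[str] = []
    for si, sub_seed in enumerate(seeds):
        subject_id = f"S{si + 1:02d}"
        session = simulate_session(cfg.generator, mont, subject_id=subject_id,
                                   seed=sub_seed)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            sf = extract_subject_features(session, cfg)
            n_epochs[subject_id] = len(sf.labels)
            for chrom, feats in sf.blocks.items():
                results.extend(
                    evaluate(feats, sf.labels, sf.landing_ids,
                             chromophore=chrom, subject_id=subject_id,
                             pairs=cfg.evaluate_pairs,
                             shrinkage=cfg.shrinkage,
                             global_zscore=cfg.global_zscore))
        caught.extend(f"{subject_id}: {w.message}" for w in wlist)

    n_test_total = None
    if n_epochs:
        n_test_total = max(n_epochs.values())
    spec = SignificanceSpec(n=n_test_total or 96, alpha=cfg.alpha)
    threshold = chance_threshold(spec)
    report = RunReport(config=_config_dict(cfg), chance_threshold_pct=threshold,
                       results=results, n_epochs_per_subject=n_epochs,
                       warnings=caught, elapsed_s=time.time() - t0)
    if out_dir is not None:
        write_artifacts(report, out_dir)
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    def conv(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, dict):
            return {k: conv(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [conv(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    return conv(dataclasses.asdict(cfg))


def write_artifacts(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.results_frame().to_csv(out / "results.csv", index=False)
    report.summary_table().to_csv(out / "results_summary.csv", index=False)
    payload = {
        "version": __version__,
        "config": report.config,
        "chance_threshold_pct": report.chance_threshold_pct,
        "n_epochs_per_subject": report.n_epochs_per_subject,
        "warnings": report.warnings,
        "elapsed_s": report.elapsed_s,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))


def mean_accuracy(report: RunReport, feature_set: str,
                  chromophore: str = "HbO") -> float:
    """Group-mean accuracy across subjects for one (feature set, chromophore)."""
    vals = [r.mean_accuracy for r in report.results
            if r.feature_set == feature_set and r.chromophore == chromophore]
    if not vals:
        raise KeyError(f"no results for {feature_set!r} / {chromophore!r}")
    return float(np.mean(vals))
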