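"""Optode montage and region-of-interest partition.

The default layout mirrors a two-device tandem recording covering prefrontal
and parieto-occipital cortex: 8 sources + 8 detectors per device, paired into
42 channels (7 per region) over 6 regions of interest, sampled at 7.8125 Hz
with 760/850 nm LED pairs at a 3 cm source-detector separation.
"""

from __future__ import annotations

from dataclasses import dataclass

ROI_LABELS = (
    "Frontal-Left",
    "Fronto-Central",
    "Frontal-Right",
    "Occipital-Left",
    "Occipito-Central",
    "Occipital-Right",
)

DEFAULT_SAMPLING_RATE = 7.8125  # Hz
DEFAULT_WAVELENGTHS = (760.0, 850.0)  # nm
DEFAULT_SD_DISTANCE = 3.0  # cm


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    channel_id: str
    source: str
    detector: str
    roi: str


@dataclass(frozen=True)
class Montage:
    channels: tuple[Channel, ...]
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    sd_distance: float = DEFAULT_SD_DISTANCE

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise ValueError("montage requires exactly two wavelengths")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in montage")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def rois(self) -> list[str]:
        """ROI labels in first-appearance (canonical) order."""
        seen: dict[str, None] = {}
        for c in self.channels:
            seen.setdefault(c.roi, None)
        return list(seen)

    def roi_partition(self) -> "ROIPartition":
        return ROIPartition(
            channel_to_roi={c.channel_id: c.roi for c in self.channels},
            rois=tuple(self.rois),
        )


@dataclass
class ROIPartition:
    """Total mapping channel id -> ROI label, with canonical ROI order."""

    channel_to_roi: dict[str, str]
    rois: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(self.channel_to_roi.values()) - set(self.rois)
        if missing:
            raise ValueError(f"channels mapped to unknown ROIs: {sorted(missing)}")
        for roi in self.rois:
            if roi not in self.channel_to_roi.values():
                raise ValueError(f"empty ROI {roi!r}")

    def members(self, roi: str) -> list[str]:
        return [ch for ch, r in self.channel_to_roi.items() if r == roi]


def build_default_montage() -> Montage:
    """Default 42-channel, 6-ROI montage (7 channels per region).

    Channel/source/detector identifiers follow the ``S{i}`` / ``D{j}``
    convention with device-local numbering (frontal device: S1-S8/D1-D8,
    occipital device: S9-S16/D9-D16).
    """
    channels: list[Channel] = []
    # 21 source-detector pairings per device, split into three 7-channel ROIs.
    # Pairing pattern: each source talks to its neighbouring detectors.
    pairs = [
        (1, 1), (1, 2), (2, 1), (2, 2), (2, 3), (3, 2), (3, 3),   # left
        (3, 4), (4, 3), (4, 4), (4, 5), (5, 4), (5, 5), (5, 6),   # central
        (6, 5), (6, 6), (6, 7), (7, 6), (7, 7), (8, 7), (8, 8),   # right
    ]
    for dev, rois in ((0, ROI_LABELS[:3]), (1, ROI_LABELS[3:])):
        off = 8 * dev
        for k, (s, d) in enumerate(pairs):
            roi = rois[k // 7]
            idx = dev * 21 + k + 1
            channels.append(
                Channel(
                    channel_id=f"C{idx:02d}",
                    source=f"S{s + off}",
                    detector=f"D{d + off}",
                    roi=roi,
                )
            )
    return Montage(channels=tuple(channels))


def build_montage(n_per_roi: int, rois: tuple[str, ...] = ROI_LABELS,
                  sampling_rate: float = DEFAULT_SAMPLING_RATE) -> Montage:
    """Reduced/custom montage: ``n_per_roi`` channels in each listed ROI.

    Used for scaled-down simulation studies; sources/detectors are synthetic
    one-per-channel identifiers.
    """
    channels = []
    idx = 0
    for roi in rois:
        for _ in range(n_per_roi):
            idx += 1
            channels.append(
                Channel(f"C{idx:02d}", f"S{idx}", f"D{idx}", roi)
            )
    return Montage(channels=tuple(channels), sampling_rate=sampling_rate)
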