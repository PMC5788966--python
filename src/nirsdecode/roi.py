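"""Reduce channel-level features to region-of-interest (ROI) level.

Oxygenation features: unweighted mean over the member channels of each ROI
(42 channels -> 6 values per feature). Connectivity features: unweighted mean
over all channel pairs connecting a given (unordered) ROI pair, keeping the
within-ROI terms, so 6 ROIs yield C(6,2) + 6 = 21 values per measure.
Between-ROI terms come first, in canonical ROI order, then within-ROI terms,
so feature indices are stable across runs.
"""

from __future__ import annotations

import numpy as np

from .montage import ROIPartition


def roi_pair_labels(partition: ROIPartition) -> list[tuple[str, str]]:
    """Canonical ROI-pair order: between-ROI pairs first, then within-ROI."""
    rois = list(partition.rois)
    between = [(rois[i], rois[j]) for i in range(len(rois))
               for j in range(i + 1, len(rois))]
    within = [(r, r) for r in rois]
    return between + within


def reduce_oxygenation(values: dict[str, float] | np.ndarray,
                       channel_ids: list[str],
                       partition: ROIPartition) -> np.ndarray:
    """Mean of per-channel values within each ROI, in canonical ROI order.

    ``values`` is either a channel_id -> value mapping or an array aligned
    with ``channel_ids``; the last axis must be channels.
    """
    if isinstance(values, dict):
        arr = np.asarray([values[c] for c in channel_ids], dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != len(channel_ids):
        raise ValueError("values do not align with channel_ids")
    unmapped = [c for c in channel_ids if c not in partition.channel_to_roi]
    if unmapped:
        raise ValueError(f"channels without ROI assignment: {unmapped}")
    out = []
    for roi in partition.rois:
        idx = [i for i, c in enumerate(channel_ids)
               if partition.channel_to_roi[c] == roi]
        if not idx:
            raise ValueError(f"ROI {roi!r} has no member channels")
        out.append(arr[..., idx].mean(axis=-1))
    return np.stack(out, axis=-1)


def reduce_connectivity(pair_values: dict[tuple[str, str], float] | np.ndarray,
                        pairs: list[tuple[str, str]],
                        partition: ROIPartition) -> np.ndarray:
    """Mean of channel-pair values per unordered ROI pair (within-ROI kept).

    ``pair_values`` is a (channel_a, channel_b) -> value mapping or an array
    aligned with ``pairs`` on the last axis. Output follows
    :func:`roi_pair_labels` order; every channel pair of the montage must be
    present.
    """
    if isinstance(pair_values, dict):
        arr = np.asarray([pair_values[p] for p in pairs], dtype=float)
    else:
        arr = np.asarray(pair_values, dtype=float)
    if arr.shape[-1] != len(pairs):
        raise ValueError("pair_values do not align with pairs")

    c2r = partition.channel_to_roi
    labels = roi_pair_labels(partition)
    groups: dict[tuple[str, str], list[int]] = {lab: [] for lab in labels}
    for k, (a, b) in enumerate(pairs):
        ra, rb = c2r[a], c2r[b]
        key = (ra, rb) if (ra, rb) in groups else (rb, ra)
        groups[key].append(k)

    # completeness: every expected channel pair must be covered
    channels = sorted(c2r)
    expected = len(channels) * (len(channels) - 1) // 2
    if len(pairs) != expected:
        raise ValueError(
            f"{len(pairs)} pair values given but the montage has {expected} "
            "channel pairs")

    out = []
    for lab in labels:
        idx = groups[lab]
        if not idx:
            raise ValueError(f"no channel pairs connect ROI pair {lab}")
        out.append(arr[..., idx].mean(axis=-1))
    return np.stack(out, axis=-1)
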