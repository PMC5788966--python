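"""SNIRF (Shared Near Infrared File Format, v1.0) reading and writing.

Implemented directly on HDF5 via h5py. Each landing is stored as its own
``/nirs{i}`` element with a continuous-wave amplitude data block
(``dataType = 1``); the condition label is carried as the landing's single
stimulus entry spanning the whole landing. ``validate_snirf`` is an internal
structural checker for the subset of the SNIRF specification this package
reads and writes.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import h5py

from .montage import Channel, Montage
from .synth import GroundTruth, Landing, RawSession

_VARLEN_STR = h5py.string_dtype(encoding="utf-8")


def _optode_positions(labels: list[str], z: float) -> np.ndarray:
    # synthetic coordinates: optodes on a line, 3 cm apart; enough for round-trip
    return np.array([[3.0 * i, 0.0, z] for i in range(len(labels))])


def _write_str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=value, dtype=_VARLEN_STR)


def write_snirf(session: RawSession, path: str) -> None:
    """Write a session as a SNIRF v1.0 file, one /nirs element per landing."""
    if not session.landings:
        raise ValueError("session has no landings")
    mont = session.montage
    sources = sorted({c.source for c in mont.channels},
                     key=lambda s: int(s.lstrip("SD")))
    detectors = sorted({c.detector for c in mont.channels},
                       key=lambda s: int(s.lstrip("SD")))
    src_idx = {s: i + 1 for i, s in enumerate(sources)}
    det_idx = {d: i + 1 for i, d in enumerate(detectors)}

    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        for li, landing in enumerate(session.landings, start=1):
            nirs = f.create_group(f"nirs{li}")

            meta = nirs.create_group("metaDataTags")
            _write_str(meta, "SubjectID", session.subject_id)
            _write_str(meta, "MeasurementDate", _dt.date(2020, 1, 1).isoformat())
            _write_str(meta, "MeasurementTime", "00:00:00")
            _write_str(meta, "LengthUnit", "cm")
            _write_str(meta, "TimeUnit", "s")
            _write_str(meta, "FrequencyUnit", "Hz")
            _write_str(meta, "nirsdecodeCondition", landing.condition)

            probe = nirs.create_group("probe")
            probe.create_dataset("wavelengths",
                                 data=np.asarray(mont.wavelengths, dtype=float))
            probe.create_dataset("sourcePos3D", data=_optode_positions(sources, 10.0))
            probe.create_dataset("detectorPos3D", data=_optode_positions(detectors, 0.0))
            probe.create_dataset("sourceLabels",
                                 data=np.array(sources, dtype=_VARLEN_STR))
            probe.create_dataset("detectorLabels",
                                 data=np.array(detectors, dtype=_VARLEN_STR))

            n_wl, n_ch, n_t = landing.intensity.shape
            t = np.arange(n_t) / mont.sampling_rate
            # column order: all channels at wavelength 1, then wavelength 2
            series = np.concatenate(
                [landing.intensity[w].T for w in range(n_wl)], axis=1)
            data = nirs.create_group("data1")
            data.create_dataset("dataTimeSeries", data=series)
            data.create_dataset("time", data=t)
            k = 0
            for w in range(n_wl):
                for ch in mont.channels:
                    k += 1
                    ml = data.create_group(f"measurementList{k}")
                    ml.create_dataset("sourceIndex", data=src_idx[ch.source],
                                      dtype="i4")
                    ml.create_dataset("detectorIndex", data=det_idx[ch.detector],
                                      dtype="i4")
                    ml.create_dataset("wavelengthIndex", data=w + 1, dtype="i4")
                    ml.create_dataset("dataType", data=1, dtype="i4")
                    ml.create_dataset("dataTypeIndex", data=1, dtype="i4")
                    _write_str(ml, "dataTypeLabel", ch.roi)

            stim = nirs.create_group("stim1")
            _write_str(stim, "name", landing.condition)
            stim.create_dataset("data",
                                data=np.array([[0.0, landing.duration_s, 1.0]]))


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path: str, roi_map: dict[str, str] | None = None) -> RawSession:
    """Read a SNIRF file written by :func:`write_snirf` back into a session.

    ``roi_map`` optionally overrides the channel -> ROI assignment; by default
    the per-measurement ``dataTypeLabel`` written by this package is used.
    """
    with h5py.File(path, "r") as f:
        nirs_keys = sorted((k for k in f if k.startswith("nirs")),
                           key=lambda k: int(k[4:] or 1))
        if not nirs_keys:
            raise ValueError(f"{path}: no /nirs element")
        landings: list[Landing] = []
        montage: Montage | None = None
        conditions: list[str] = []
        subject = "S01"
        for key in nirs_keys:
            nirs = f[key]
            meta = nirs["metaDataTags"]
            subject = _read_str(meta["SubjectID"])
            condition = _read_str(nirs["stim1/name"])
            wavelengths = tuple(np.asarray(nirs["probe/wavelengths"]).tolist())
            src_labels = [x.decode() if isinstance(x, bytes) else str(x)
                          for x in nirs["probe/sourceLabels"][()]]
            det_labels = [x.decode() if isinstance(x, bytes) else str(x)
                          for x in nirs["probe/detectorLabels"][()]]
            data = nirs["data1"]
            t = np.asarray(data["time"])
            fs = 1.0 / np.median(np.diff(t))
            series = np.asarray(data["dataTimeSeries"])
            ml_keys = sorted((k for k in data if k.startswith("measurementList")),
                             key=lambda k: int(k[len("measurementList"):]))
            per_wl: dict[int, list[tuple[str, str, str]]] = {}
            cols: dict[int, list[int]] = {}
            for col, k in enumerate(ml_keys):
                ml = data[k]
                w = int(ml["wavelengthIndex"][()])
                s = src_labels[int(ml["sourceIndex"][()]) - 1]
                d = det_labels[int(ml["detectorIndex"][()]) - 1]
                roi = _read_str(ml["dataTypeLabel"]) if "dataTypeLabel" in ml else ""
                per_wl.setdefault(w, []).append((s, d, roi))
                cols.setdefault(w, []).append(col)
            chans = per_wl[1]
            if montage is None:
                channels = []
                for i, (s, d, roi) in enumerate(chans):
                    cid = f"C{i + 1:02d}"
                    if roi_map is not None:
                        roi = roi_map.get(cid, roi_map.get(f"{s}-{d}", roi))
                    channels.append(Channel(cid, s, d, roi))
                montage = Montage(channels=tuple(channels), sampling_rate=round(fs, 6),
                                  wavelengths=(float(wavelengths[0]),
                                               float(wavelengths[1])))
            intensity = np.stack(
                [series[:, cols[w]].T for w in sorted(cols)], axis=0)
            landings.append(Landing(condition=condition, intensity=intensity,
                                    duration_s=float(t[-1] - t[0] + np.median(np.diff(t)))))
            conditions.append(condition)
        gt = GroundTruth(condition_order=conditions, coupling={}, artifacts=[],
                         seed=-1)
        return RawSession(montage=montage, landings=landings, ground_truth=gt,
                          subject_id=subject)


def validate_snirf(path: str) -> list[str]:
    """Structural check against the SNIRF v1.0 subset used here.

    Returns a list of problems; an empty list means the file conforms.
    """
    issues: list[str] = []
    with h5py.File(path, "r") as f:
        if "formatVersion" not in f:
            issues.append("missing /formatVersion")
        nirs_keys = [k for k in f if k.startswith("nirs")]
        if not nirs_keys:
            issues.append("no /nirs element")
        for key in nirs_keys:
            nirs = f[key]
            for req in ("metaDataTags", "probe", "data1"):
                if req not in nirs:
                    issues.append(f"/{key}: missing {req}")
            if "metaDataTags" in nirs:
                for tag in ("SubjectID", "MeasurementDate", "MeasurementTime",
                            "LengthUnit", "TimeUnit", "FrequencyUnit"):
                    if tag not in nirs["metaDataTags"]:
                        issues.append(f"/{key}/metaDataTags: missing {tag}")
            if "probe" in nirs:
                for req in ("wavelengths", "sourcePos3D", "detectorPos3D"):
                    if req not in nirs["probe"]:
                        issues.append(f"/{key}/probe: missing {req}")
            if "data1" not in nirs:
                continue
            data = nirs["data1"]
            for req in ("dataTimeSeries", "time"):
                if req not in data:
                    issues.append(f"/{key}/data1: missing {req}")
            ml_keys = [k for k in data if k.startswith("measurementList")]
            if not ml_keys:
                issues.append(f"/{key}/data1: no measurementList")
            if "dataTimeSeries" in data and ml_keys:
                if data["dataTimeSeries"].shape[1] != len(ml_keys):
                    issues.append(
                        f"/{key}/data1: dataTimeSeries columns != measurementList count")
            if "dataTimeSeries" in data and "time" in data:
                if data["dataTimeSeries"].shape[0] != data["time"].shape[0]:
                    issues.append(f"/{key}/data1: time length mismatch")
            for k in ml_keys:
                ml = data[k]
                for req in ("sourceIndex", "detectorIndex", "wavelengthIndex",
                            "dataType", "dataTypeIndex"):
                    if req not in ml:
                        issues.append(f"/{key}/data1/{k}: missing {req}")
    return issues
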