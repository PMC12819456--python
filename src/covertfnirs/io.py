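"""Reading and writing recordings: SNIRF (HDF5) and a plain-text TSV dialect.

SNIRF files follow the published HDF5 layout (`/nirs1/data1`, `/nirs1/probe`,
stim groups); package-specific channel metadata (ROI labels, short-channel
flags, separations) travels in a JSON metaDataTags entry. The TSV dialect is
one table per recording (a `time` column plus one `S_D_wavelength` column per
channel x wavelength) with a JSON sidecar holding montage, events and
metadata; both formats round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError
from .recording import (Channel, Epoch, EventSchedule, Optode, Probe,
                        Recording)


def _probe_to_dict(probe: Probe) -> dict:
    return {
        "sources": [{"label": o.label, "position": list(o.position)}
                    for o in probe.sources],
        "detectors": [{"label": o.label, "position": list(o.position),
                       "is_short": bool(f)}
                      for o, f in zip(probe.detectors, probe.short_detector_flags)],
        "channels": [{"source": c.source, "detector": c.detector,
                      "separation": c.separation, "roi": c.roi,
                      "is_short": c.is_short} for c in probe.channels],
    }


def _probe_from_dict(d: dict) -> Probe:
    try:
        sources = tuple(Optode(s["label"], tuple(s["position"])) for s in d["sources"])
        detectors = tuple(Optode(s["label"], tuple(s["position"])) for s in d["detectors"])
        flags = tuple(bool(s["is_short"]) for s in d["detectors"])
        channels = tuple(Channel(c["source"], c["detector"], float(c["separation"]),
                                 c["roi"], bool(c["is_short"])) for c in d["channels"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed probe description: missing {exc}") from exc
    return Probe(sources, detectors, flags, channels)


def _events_to_list(events: EventSchedule) -> list:
    return [[ep.onset, ep.duration, ep.condition] for ep in events.epochs]


def _events_from_list(rows: list, total_duration: float) -> EventSchedule:
    eps = tuple(Epoch(float(o), float(d), str(c)) for o, d, c in rows)
    return EventSchedule(eps, float(total_duration))


def _column_names(probe: Probe, wavelengths) -> list[str]:
    return [f"{ch.name}_{int(round(w))}"
            for ch in probe.channels for w in wavelengths]


def write_recording(recording: Recording, path: str | Path,
                    format: str | None = None) -> Path:
    """Write a recording; format inferred from the extension when omitted
    (.snirf/.h5 -> SNIRF, .tsv -> TSV + JSON sidecar)."""
    recording.validate()
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        _write_snirf(recording, path)
    elif fmt == "tsv":
        _write_tsv(recording, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read and validate a recording from SNIRF or the TSV dialect."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        rec = _read_snirf(path)
    elif fmt == "tsv":
        rec = _read_tsv(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    rec.validate()
    return rec


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".snirf", ".h5", ".hdf5"):
        return "snirf"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer format from {path.name!r}")


# ---------------------------------------------------------------- TSV dialect

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_tsv(recording: Recording, path: Path) -> None:
    probe = recording.probe
    n, n_ch, _ = recording.intensity.shape
    flat = recording.intensity.reshape(n, n_ch * 2)
    df = pd.DataFrame(flat, columns=_column_names(probe, recording.wavelengths))
    df.insert(0, "time", recording.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "wavelengths": list(recording.wavelengths),
        "subject_id": recording.subject_id,
        "session_index": recording.session_index,
        "probe": _probe_to_dict(probe),
        "events": _events_to_list(recording.events),
        "total_duration": recording.events.total_duration,
        "meta": recording.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_tsv(path: Path) -> Recording:
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side.name}")
    meta = json.loads(side.read_text())
    for key in ("sampling_rate", "wavelengths", "probe", "events"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    wavelengths = tuple(float(w) for w in meta["wavelengths"])
    if len(wavelengths) != 2:
        raise FormatError("sidecar field 'wavelengths' must list two wavelengths")
    probe = _probe_from_dict(meta["probe"])
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = _column_names(probe, wavelengths)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"TSV missing channel columns {missing[:3]}")
    n = len(df)
    intensity = df[cols].to_numpy(float).reshape(n, len(probe.channels), 2)
    events = _events_from_list(meta["events"], meta["total_duration"])
    return Recording(probe, intensity, wavelengths, float(meta["sampling_rate"]),
                     events, subject_id=meta.get("subject_id", "sub-01"),
                     session_index=int(meta.get("session_index", 1)),
                     meta=meta.get("meta", {}))


# --------------------------------------------------------------------- SNIRF

_STR = h5py.string_dtype(encoding="utf-8")


def _write_snirf(recording: Recording, path: Path) -> None:
    probe = recording.probe
    n, n_ch, _ = recording.intensity.shape
    src_labels = [o.label for o in probe.sources]
    det_labels = [o.label for o in probe.detectors]
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs1")
        tags = nirs.create_group("metaDataTags")
        tags.create_dataset("SubjectID", data=recording.subject_id, dtype=_STR)
        tags.create_dataset("MeasurementDate", data="unknown", dtype=_STR)
        tags.create_dataset("MeasurementTime", data="unknown", dtype=_STR)
        tags.create_dataset("LengthUnit", data="cm", dtype=_STR)
        tags.create_dataset("TimeUnit", data="s", dtype=_STR)
        tags.create_dataset("FrequencyUnit", data="Hz", dtype=_STR)
        extra = {
            "sampling_rate": recording.sampling_rate,
            "session_index": recording.session_index,
            "channels": _probe_to_dict(probe)["channels"],
            "short_detector_flags": [bool(x) for x in probe.short_detector_flags],
            "events": _events_to_list(recording.events),
            "total_duration": recording.events.total_duration,
            "meta": recording.meta,
        }
        tags.create_dataset("covertfnirsJSON", data=json.dumps(extra), dtype=_STR)

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries",
                            data=recording.intensity.reshape(n, n_ch * 2))
        data.create_dataset("time", data=recording.times)
        k = 1
        for ci, ch in enumerate(probe.channels):
            for wi in (1, 2):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex",
                                  data=src_labels.index(ch.source) + 1)
                ml.create_dataset("detectorIndex",
                                  data=det_labels.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1

        pg = nirs.create_group("probe")
        pg.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))
        pg.create_dataset("sourcePos3D",
                          data=np.array([o.position for o in probe.sources]))
        pg.create_dataset("detectorPos3D",
                          data=np.array([o.position for o in probe.detectors]))
        pg.create_dataset("sourceLabels", data=src_labels, dtype=_STR)
        pg.create_dataset("detectorLabels", data=det_labels, dtype=_STR)

        for i, cond in enumerate(("task", "rest"), start=1):
            rows = [[ep.onset, ep.duration, 1.0]
                    for ep in recording.events.epochs if ep.condition == cond]
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=cond, dtype=_STR)
            stim.create_dataset("data", data=np.asarray(rows, float).reshape(-1, 3))


def _require(group, key: str, context: str):
    if key not in group:
        raise FormatError(f"SNIRF file missing {context} '{key}'")
    return group[key]


def _read_snirf(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs1", "group")
        pg = _require(nirs, "probe", "group")
        wl = np.asarray(_require(pg, "wavelengths", "probe field")[()], float)
        if wl.size != 2:
            raise FormatError("SNIRF field 'wavelengths' must list two wavelengths")
        src_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in _require(pg, "sourceLabels", "probe field")[()]]
        det_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in _require(pg, "detectorLabels", "probe field")[()]]
        src_pos = np.asarray(_require(pg, "sourcePos3D", "probe field")[()], float)
        det_pos = np.asarray(_require(pg, "detectorPos3D", "probe field")[()], float)

        tags = _require(nirs, "metaDataTags", "group")
        subject = _require(tags, "SubjectID", "metadata")[()]
        subject = subject.decode() if isinstance(subject, bytes) else str(subject)
        extra_raw = _require(tags, "covertfnirsJSON", "metadata")[()]
        extra = json.loads(extra_raw.decode() if isinstance(extra_raw, bytes)
                           else extra_raw)

        data = _require(nirs, "data1", "group")
        series = np.asarray(_require(data, "dataTimeSeries", "data field")[()], float)
        time = np.asarray(_require(data, "time", "data field")[()], float)

    sources = tuple(Optode(lab, tuple(p)) for lab, p in zip(src_labels, src_pos))
    detectors = tuple(Optode(lab, tuple(p)) for lab, p in zip(det_labels, det_pos))
    flags = tuple(bool(x) for x in extra["short_detector_flags"])
    channels = tuple(Channel(c["source"], c["detector"], float(c["separation"]),
                             c["roi"], bool(c["is_short"]))
                     for c in extra["channels"])
    probe = Probe(sources, detectors, flags, channels)
    n_ch = len(channels)
    if series.shape[1] != n_ch * 2:
        raise FormatError(
            f"dataTimeSeries has {series.shape[1]} columns, expected {n_ch * 2}")
    intensity = series.reshape(series.shape[0], n_ch, 2)
    events = _events_from_list(extra["events"], extra["total_duration"])
    if "sampling_rate" in extra:
        sampling_rate = float(extra["sampling_rate"])
    elif len(time) > 1:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    else:
        sampling_rate = 1.0
    return Recording(probe, intensity, (float(wl[0]), float(wl[1])),
                     float(sampling_rate), events, subject_id=subject,
                     session_index=int(extra.get("session_index", 1)),
                     meta=extra.get("meta", {}))
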