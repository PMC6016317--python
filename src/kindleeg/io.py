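"""Signal and annotation I/O.

Signals travel as single-column CSV (header ``voltage_uv``) with a JSON
sidecar (``<stem>.json``) holding sampling rate, start time and label; EDF
files are read through :mod:`mne` when it is installed. Annotations and
detected events are tab-separated tables.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .records import ADSegment, EEGRecord, StageEvent

EVENT_COLUMNS = ["animal_id", "group", "day", "onset_s", "duration_s", "racine_stage", "phase"]
DETECTION_COLUMNS = ["onset_s", "duration_s", "matched_stage", "phase", "flag"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal_csv(record: EEGRecord, path) -> Path:
    """Write a record as CSV plus a JSON sidecar with the sampling metadata."""
    path = Path(path)
    pd.DataFrame({"voltage_uv": record.samples}).to_csv(path, index=False)
    meta = {
        "sampling_rate": record.sampling_rate,
        "start_time": record.start_time,
        "label": record.label,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_signal(path, sampling_rate: float | None = None) -> EEGRecord:
    """Read a signal from CSV (+ JSON sidecar) or EDF.

    For CSV without a sidecar, ``sampling_rate`` must be supplied. EDF
    reading requires :mod:`mne`; only the first channel is used and volts
    are converted to µV.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ConfigurationError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data(picks=[0])[0] * 1e6
        return EEGRecord(samples=data, sampling_rate=float(raw.info["sfreq"]), label=path.stem)
    frame = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fs = meta.get("sampling_rate", sampling_rate)
    if fs is None:
        raise ConfigurationError(f"no sampling rate for {path}: missing sidecar and argument")
    col = "voltage_uv" if "voltage_uv" in frame.columns else frame.columns[0]
    return EEGRecord(
        samples=frame[col].to_numpy(dtype=float),
        sampling_rate=float(fs),
        start_time=float(meta.get("start_time", 0.0)),
        label=str(meta.get("label", path.stem)),
    )


def write_events_tsv(events: list[StageEvent], path) -> Path:
    path = Path(path)
    rows = [
        {
            "animal_id": e.animal_id,
            "group": e.group,
            "day": e.day,
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "racine_stage": e.racine_stage,
            "phase": e.phase,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path) -> list[StageEvent]:
    frame = pd.read_csv(path, sep="\t")
    return [
        StageEvent(
            onset_s=float(r.onset_s),
            duration_s=float(r.duration_s),
            racine_stage=int(r.racine_stage),
            animal_id=str(r.animal_id),
            group=str(r.group),
            day=int(r.day),
        )
        for r in frame.itertuples()
    ]


def write_detections_tsv(segments: list[ADSegment], path) -> Path:
    path = Path(path)
    rows = [
        {
            "onset_s": s.onset,
            "duration_s": s.add,
            "matched_stage": s.racine_stage if s.matched else "",
            "phase": s.phase if s.matched else "",
            "flag": "" if s.matched else "unmatched",
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path
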