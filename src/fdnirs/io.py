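"""On-disk formats: recording CSV, event JSON, and stage output tables.

Recording CSV: one row per sample, columns ``time_s`` then
``IDC_{wavelength}_{distance}``, ``IAC_...``, ``phase_...`` for every
wavelength (nm) and distance (cm), e.g. ``IAC_690_2.5``. Event JSON carries
the schedule, TBS pulse times and (for synthetic data) labelled artifact
windows; the ground-truth sidecar records everything needed to regenerate a
synthetic session. Readers validate the schema and name the offending
column or row in errors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .extinction import ExtinctionTable
from .types import (
    ChromophoreSeries,
    Geometry,
    RawFDRecording,
    SessionSchedule,
    StimulusEvent,
)


class SchemaError(ValueError):
    """Out-of-schema input; message names the file/column/row at fault."""


def _fmt(x: float) -> str:
    return format(float(x), "g")


def _channel_columns(geometry: Geometry) -> list[str]:
    cols = []
    for kind in ("IDC", "IAC", "phase"):
        for w in geometry.wavelengths_nm:
            for r in geometry.distances_cm:
                cols.append(f"{kind}_{_fmt(w)}_{_fmt(r)}")
    return cols


def write_recording_csv(recording: RawFDRecording, path) -> None:
    g = recording.geometry
    n = recording.n_samples
    data = {"time_s": recording.time_s}
    for kind, arr in (("IDC", recording.idc), ("IAC", recording.iac),
                      ("phase", recording.phase)):
        for i, w in enumerate(g.wavelengths_nm):
            for j, r in enumerate(g.distances_cm):
                data[f"{kind}_{_fmt(w)}_{_fmt(r)}"] = arr[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(path, geometry: Geometry | None = None,
                       fs_hz: float = 10.4, meta: dict | None = None,
                       phase_in_degrees: bool = False) -> RawFDRecording:
    geometry = geometry if geometry is not None else Geometry()
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'time_s'")
    expected = _channel_columns(geometry)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel columns {missing[:4]}"
                          + ("..." if len(missing) > 4 else ""))
    for col in ["time_s"] + expected:
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(f"{path}: non-numeric value in column '{col}', row {row}")
    n = len(df)
    nw, nd = geometry.n_wavelengths, geometry.n_distances

    def grab(kind):
        out = np.empty((n, nw, nd))
        for i, w in enumerate(geometry.wavelengths_nm):
            for j, r in enumerate(geometry.distances_cm):
                out[:, i, j] = df[f"{kind}_{_fmt(w)}_{_fmt(r)}"].to_numpy(dtype=float)
        return out

    phase = grab("phase")
    if phase_in_degrees:
        phase = np.deg2rad(phase)
    return RawFDRecording(
        time_s=df["time_s"].to_numpy(dtype=float),
        idc=grab("IDC"), iac=grab("IAC"), phase=phase,
        geometry=geometry, fs_hz=fs_hz, meta=dict(meta or {}),
    )


def write_event_json(schedule: SessionSchedule, path,
                     artifact_windows_s=()) -> None:
    payload = {
        "subject": schedule.subject_id,
        "paradigm": schedule.paradigm,
        "seed": schedule.seed,
        "events": [
            {"onset_s": e.onset_s, "modality": e.modality,
             "epoch": e.epoch, "block": e.block_index}
            for e in schedule.events
        ],
        "tbs_pulse_times_s": [float(t) for t in schedule.tbs_pulse_times_s],
        "artifact_windows_s": [[float(a), float(b)] for a, b in artifact_windows_s],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_event_json(path) -> tuple[SessionSchedule, list[tuple[float, float]]]:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("subject", "paradigm", "events"):
        if key not in payload:
            raise SchemaError(f"{path}: missing required key '{key}'")
    events = []
    for i, ev in enumerate(payload["events"]):
        try:
            events.append(StimulusEvent(
                onset_s=float(ev["onset_s"]), modality=str(ev["modality"]),
                epoch=str(ev["epoch"]), paradigm=str(payload["paradigm"]),
                block_index=int(ev["block"]),
            ))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: bad event at index {i}: {exc}") from exc
    schedule = SessionSchedule(
        events=events,
        tbs_pulse_times_s=np.asarray(payload.get("tbs_pulse_times_s", []), dtype=float),
        paradigm=str(payload["paradigm"]),
        subject_id=str(payload["subject"]),
        seed=int(payload.get("seed", 0)),
    )
    windows = [tuple(w) for w in payload.get("artifact_windows_s", [])]
    return schedule, windows


def write_truth_json(path, *, baseline_uM, hrf, noise, musp_cm,
                     extinction: ExtinctionTable) -> None:
    """Ground-truth sidecar for a synthetic session (synthetic data only)."""
    payload = {
        "baseline_uM": {"HbO2": float(baseline_uM[0]), "HHb": float(baseline_uM[1])},
        "hrf": hrf.to_dict(),
        "noise": noise.to_dict(),
        "musp_cm": [float(m) for m in musp_cm],
        "extinction_1_per_mM_cm": extinction.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def write_chromophore_csv(series: ChromophoreSeries, path) -> None:
    pd.DataFrame({
        "time_s": series.time_s,
        "HbO2_uM": series.hbo2_uM,
        "HHb_uM": series.hhb_uM,
        "tHb_uM": series.thb_uM,
        "valid": series.valid.astype(int),
    }).to_csv(path, index=False, float_format="%.17g")


def read_chromophore_csv(path, fs_hz: float = 10.4) -> ChromophoreSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time_s", "HbO2_uM", "HHb_uM", "tHb_uM", "valid"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return ChromophoreSeries(
        time_s=df["time_s"].to_numpy(dtype=float),
        hbo2_uM=df["HbO2_uM"].to_numpy(dtype=float),
        hhb_uM=df["HHb_uM"].to_numpy(dtype=float),
        thb_uM=df["tHb_uM"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        fs_hz=fs_hz,
    )


def write_diagnostics_csv(slopes, optical, geometry: Geometry, time_s, path) -> None:
    data = {"time_s": time_s}
    for i, w in enumerate(geometry.wavelengths_nm):
        tag = _fmt(w)
        for name, arr in (
            ("SAC", slopes.sac), ("SDC", slopes.sdc), ("Sphase", slopes.sphase),
            ("R2_AC", slopes.r2_ac), ("R2_DC", slopes.r2_dc),
            ("R2_phase", slopes.r2_phase),
            ("mua", optical.mua), ("musp", optical.musp),
        ):
            data[f"{name}_{tag}"] = arr[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


SEGMENT_COLUMNS = [
    "subject", "paradigm", "epoch", "modality", "signal", "block_index",
    "onset_s", "mean_normalized_change_pct", "valid_fraction", "kept", "reason",
]


def write_segment_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False, columns=SEGMENT_COLUMNS,
                     float_format="%.17g")


def read_segment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"reason": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["kept"] = df["kept"].astype(bool)
    df["mean_normalized_change_pct"] = pd.to_numeric(
        df["mean_normalized_change_pct"], errors="coerce"
    )
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths, manifest_path) -> dict:
    manifest = {str(Path(p).name): file_sha256(p) for p in paths}
    Path(manifest_path).write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
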