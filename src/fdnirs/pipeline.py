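"""End-to-end glue: simulate a session, invert it, condition it, summarize it.

These helpers chain the stage modules with consistent defaults so cohort
studies (and the command-line tool) stay one call deep:

    run = simulate_session("s01", "cTBS", seed=7)
    summaries = analyze_session(run.recording, run.schedule.events, "s01")
    results = run_comparisons(cohort_frame)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extinction import ExtinctionTable
from .inversion import DEFAULT_R2_THRESHOLD, FDMultiDistanceModel
from .preprocess import (
    DEFAULT_MAX_INVALID_FRACTION,
    DEFAULT_WINDOW_S,
    FilterSpec,
    apply_event_qc,
    apply_filter,
    design_bandpass,
    detect_artifact_windows,
    segment_events,
)
from .rng import session_seed
from .simulate import (
    DEFAULT_BASELINE_UM,
    DEFAULT_FS_HZ,
    DEFAULT_MUSP_CM,
    HemodynamicResponseModel,
    NoiseModel,
    forward_fd,
    simulate_chromophores,
)
from .schedule import make_session_schedule
from .stats import EvokedContrastResults, run_comparisons
from .types import Geometry, RawFDRecording, SessionSchedule, StimulusEvent, TissueState


@dataclass
class SessionRun:
    schedule: SessionSchedule
    tissue: TissueState
    recording: RawFDRecording


def simulate_session(
    subject_id: str,
    paradigm: str,
    seed: int,
    *,
    hrf: HemodynamicResponseModel | None = None,
    noise: NoiseModel | None = None,
    baseline_uM=DEFAULT_BASELINE_UM,
    geometry: Geometry | None = None,
    extinction: ExtinctionTable | None = None,
    musp_cm=DEFAULT_MUSP_CM,
    fs_hz: float = DEFAULT_FS_HZ,
) -> SessionRun:
    """One full synthetic session: schedule -> tissue dynamics -> raw optics."""
    geometry = geometry if geometry is not None else Geometry()
    schedule = make_session_schedule(paradigm, subject_id, seed)
    tissue = simulate_chromophores(
        schedule, hrf=hrf, noise=noise, baseline_uM=baseline_uM,
        fs_hz=fs_hz, musp_cm=musp_cm,
    )
    recording = forward_fd(
        tissue, geometry=geometry, extinction=extinction, noise=noise, seed=seed,
        meta={"subject": subject_id, "paradigm": paradigm, "seed": int(seed)},
    )
    return SessionRun(schedule=schedule, tissue=tissue, recording=recording)


def analyze_session(
    recording: RawFDRecording,
    events: list[StimulusEvent],
    subject_id: str,
    *,
    extinction: ExtinctionTable | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    filter_spec: FilterSpec | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    baseline_mode: str = "onset-sample",
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
    artifact_windows=None,
    detect_artifacts: bool = False,
) -> pd.DataFrame:
    """Raw recording + event list -> per-event summary table.

    Artifact windows default to the recording's ground-truth labels; pass
    ``detect_artifacts=True`` to use threshold detection instead (real
    recordings without labels).
    """
    filter_spec = filter_spec if filter_spec is not None else FilterSpec()
    inv = FDMultiDistanceModel(recording, extinction, r2_threshold).fit()
    kernel = design_bandpass(filter_spec, recording.fs_hz)
    filtered = apply_filter(inv.chromophores, kernel)
    segments = segment_events(
        filtered, events, window_s=window_s, baseline_mode=baseline_mode
    )
    if artifact_windows is None:
        artifact_windows = (
            detect_artifact_windows(recording)
            if detect_artifacts
            else recording.artifact_windows_s
        )
    summaries = apply_event_qc(
        segments, artifact_windows, max_invalid_fraction,
        subject=subject_id, window_s=window_s,
    )
    return pd.DataFrame([vars(s) for s in summaries])


def run_session(subject_id: str, paradigm: str, seed: int, **kwargs) -> pd.DataFrame:
    """Simulate and analyze one session; analysis keywords pass through."""
    sim_keys = {
        "hrf", "noise", "baseline_uM", "geometry", "extinction", "musp_cm", "fs_hz"
    }
    sim_kwargs = {k: v for k, v in kwargs.items() if k in sim_keys}
    ana_kwargs = {k: v for k, v in kwargs.items() if k not in sim_keys}
    if "extinction" in sim_kwargs:
        ana_kwargs.setdefault("extinction", sim_kwargs["extinction"])
    run = simulate_session(subject_id, paradigm, seed, **sim_kwargs)
    return analyze_session(run.recording, run.schedule.events, subject_id, **ana_kwargs)


def run_cohort(
    subjects: dict[str, list[str]],
    root_seed: int,
    **kwargs,
) -> pd.DataFrame:
    """Simulate/analyze every (subject, paradigm) session of a cohort.

    ``subjects`` maps subject id -> list of paradigms; per-session seeds are
    derived deterministically from ``root_seed`` and the roster position.
    """
    frames = []
    for idx, (subject_id, paradigms) in enumerate(subjects.items()):
        for paradigm in paradigms:
            seed = session_seed(root_seed, idx, paradigm)
            frames.append(run_session(subject_id, paradigm, seed, **kwargs))
    return pd.concat(frames, ignore_index=True)


def analyze_cohort(summaries: pd.DataFrame, alpha: float = 0.05) -> EvokedContrastResults:
    return run_comparisons(summaries, alpha=alpha)
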