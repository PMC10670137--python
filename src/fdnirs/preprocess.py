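"""Signal conditioning: band-pass filtering, event segmentation, event QC.

The chromophore series is band-passed 0.02-0.7 Hz with a zero-phase
Hanning windowed-sinc FIR (slow baseline deviations out, cardiac pulsation
out). Each single-pulse stimulus is then cut into a (0, 6] s segment,
expressed as percent change of the baseline value at the stimulus, and an
event is dropped when more than one third of its window failed the
raw-data quality gate, when a motion-artifact window overlaps it, or when
its baseline is numerically unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

from .types import ChromophoreSeries, EventSegment, SegmentSummary, SIGNALS, StimulusEvent

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 6.0
DEFAULT_MAX_INVALID_FRACTION = 1.0 / 3.0
DEFAULT_BASELINE_FLOOR_UM = 1e-3


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; the window shape is fixed to Hanning."""

    low_cut_hz: float = 0.02
    high_cut_hz: float = 0.7
    taps: int = 1001
    window: str = "hanning"

    def __post_init__(self) -> None:
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")
        if self.taps % 2 == 0 or self.taps < 3:
            raise ValueError("taps must be an odd integer >= 3 (symmetric kernel)")
        if self.window != "hanning":
            raise ValueError("only the Hanning window is supported")


def design_bandpass(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass kernel.

    The kernel is symmetric and mean-subtracted, so its DC gain is exactly
    zero while the passband gain stays within a fraction of a percent of
    unity.
    """
    if not (0 < spec.low_cut_hz < spec.high_cut_hz < fs_hz / 2):
        raise ValueError(
            f"cutoffs ({spec.low_cut_hz}, {spec.high_cut_hz}) Hz must lie inside "
            f"(0, fs/2 = {fs_hz / 2}) Hz"
        )
    kernel = firwin(
        spec.taps,
        [spec.low_cut_hz, spec.high_cut_hz],
        pass_zero=False,
        window="hann",
        fs=fs_hz,
    )
    return kernel - kernel.mean()


def _zero_phase(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = len(kernel) // 2
    padded = np.pad(x, half, mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def _fill_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid samples (edges: nearest valid)."""
    if valid.all():
        return x
    idx = np.arange(x.size)
    return np.interp(idx, idx[valid], x[valid])


def _dilate(mask: np.ndarray, width: int) -> np.ndarray:
    """Grow True runs of ``mask`` by ``width`` samples on both sides."""
    if width <= 0 or not mask.any():
        return mask
    hits = np.flatnonzero(mask)
    out = np.zeros_like(mask)
    lo = np.maximum(hits - width, 0)
    hi = np.minimum(hits + width + 1, mask.size)
    delta = np.zeros(mask.size + 1, dtype=int)
    np.add.at(delta, lo, 1)
    np.add.at(delta, hi, -1)
    out = np.cumsum(delta[:-1]) > 0
    return out


def apply_filter(series: ChromophoreSeries, kernel: np.ndarray) -> ChromophoreSeries:
    """Zero-phase filtering of both chromophores; tHb is re-derived as their
    sum so the additivity identity survives filtering.

    Invalid samples are linearly interpolated before convolution and the
    validity mask is dilated by half the kernel width around invalid runs,
    marking every output sample a bad input could have touched.
    """
    n = series.n_samples
    if n < kernel.size:
        raise ValueError(
            f"series of {n} samples is shorter than the minimum length "
            f"{kernel.size} (one kernel)"
        )
    valid = series.valid.astype(bool)
    if not valid.any():
        nanarr = np.full(n, np.nan)
        return ChromophoreSeries(
            time_s=series.time_s.copy(),
            hbo2_uM=nanarr.copy(), hhb_uM=nanarr.copy(), thb_uM=nanarr.copy(),
            valid=valid.copy(), fs_hz=series.fs_hz,
        )
    hbo2 = _zero_phase(_fill_invalid(series.hbo2_uM, valid), kernel)
    hhb = _zero_phase(_fill_invalid(series.hhb_uM, valid), kernel)
    new_valid = ~_dilate(~valid, kernel.size // 2)
    # the band-pass removes the mean; keep the absolute level for percent
    # normalization downstream
    levels = {name: series.level(name) for name in SIGNALS}
    return ChromophoreSeries(
        time_s=series.time_s.copy(),
        hbo2_uM=hbo2,
        hhb_uM=hhb,
        thb_uM=hbo2 + hhb,
        valid=new_valid,
        fs_hz=series.fs_hz,
        level_uM=levels,
    )


def segment_events(
    series: ChromophoreSeries,
    events: list[StimulusEvent],
    window_s: float = DEFAULT_WINDOW_S,
    baseline_mode: str = "onset-sample",
    *,
    baseline_floor_uM: float = DEFAULT_BASELINE_FLOOR_UM,
    pre_window_s: float = 0.5,
) -> list[EventSegment]:
    """Cut baseline-normalized (0, window] s segments around each stimulus.

    The subtracted baseline is the signal value at the sample nearest the
    onset (``onset-sample``) or the mean over the ``pre_window_s`` seconds
    before it (``pre-window``). The difference is expressed as percent of
    the signal's absolute concentration level (``series.level``): after the
    band-pass the trace itself is zero-mean, so the onset-sample value
    carries no absolute scale and cannot serve as the denominator. Events
    whose window runs past the end of the recording are dropped (logged); a
    level below ``baseline_floor_uM`` in magnitude flags the segment
    instead of dividing by ~0.
    """
    if baseline_mode not in ("onset-sample", "pre-window"):
        raise ValueError("baseline_mode must be 'onset-sample' or 'pre-window'")
    fs = series.fs_hz
    n = series.n_samples
    win = int(np.floor(window_s * fs))
    segments: list[EventSegment] = []
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        if i0 < 0 or i0 + win >= n:
            logger.info(
                "dropping event at %.1f s (%s/%s): window exceeds recording",
                ev.onset_s, ev.modality, ev.epoch,
            )
            continue
        sl = slice(i0 + 1, i0 + win + 1)
        window_valid = series.valid[sl].astype(bool)
        for sig in SIGNALS:
            x = series.signal(sig)
            level = series.level(sig)
            if baseline_mode == "onset-sample":
                baseline = x[i0]
                baseline_ok = bool(series.valid[i0])
            else:
                j0 = max(0, i0 - int(round(pre_window_s * fs)))
                base_slice = slice(j0, i0 + 1)
                base_valid = series.valid[base_slice]
                baseline_ok = bool(base_valid.any())
                baseline = (
                    float(np.nanmean(x[base_slice][base_valid])) if baseline_ok else np.nan
                )
            flag = ""
            if not baseline_ok:
                flag = "invalid baseline"
                normalized = np.full(win, np.nan)
            elif not np.isfinite(level) or abs(level) < baseline_floor_uM:
                flag = "unstable baseline"
                normalized = np.full(win, np.nan)
            else:
                normalized = 100.0 * (x[sl] - baseline) / abs(level)
            segments.append(
                EventSegment(
                    event=ev,
                    signal=sig,
                    normalized_pct=normalized,
                    window_valid=window_valid,
                    baseline_uM=float(baseline),
                    valid_fraction=float(window_valid.mean()) if win else 0.0,
                    flag=flag,
                )
            )
    return segments


def detect_artifact_windows(recording, k: float = 8.0, merge_gap_s: float = 0.5):
    """Threshold-based motion detection for recordings without labels.

    Flags samples where any channel's intensity jump |dIAC| or |dIDC|
    exceeds ``k`` times that channel's median absolute deviation of jumps,
    then merges flagged samples closer than ``merge_gap_s`` into windows.
    Synthetic recordings carry ground-truth labels and normally skip this.
    """
    fs = recording.fs_hz
    flags = np.zeros(recording.n_samples, dtype=bool)
    for arr in (recording.iac, recording.idc):
        d = np.abs(np.diff(arr, axis=0))  # (n-1, nw, nd)
        mad = np.median(d, axis=0, keepdims=True)
        jump = d > k * np.maximum(mad, 1e-300)
        hit = jump.any(axis=(1, 2))
        flags[1:] |= hit
        flags[:-1] |= hit
    if not flags.any():
        return []
    idx = np.flatnonzero(flags)
    windows = []
    start = prev = idx[0]
    gap = int(round(merge_gap_s * fs))
    for i in idx[1:]:
        if i - prev > gap:
            windows.append((start / fs, (prev + 1) / fs))
            start = i
        prev = i
    windows.append((start / fs, (prev + 1) / fs))
    return windows


def _overlaps(onset_s: float, window_s: float, windows) -> bool:
    end = onset_s + window_s
    return any(t0 < end and t1 > onset_s for (t0, t1) in windows)


def apply_event_qc(
    segments: list[EventSegment],
    artifact_windows=(),
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
    *,
    subject: str = "",
    window_s: float = DEFAULT_WINDOW_S,
) -> list[SegmentSummary]:
    """Apply the discard rules and summarize each event to its window mean.

    A segment is kept only if at least ``1 - max_invalid_fraction`` of its
    window passed the raw-data gate, no artifact window overlaps
    [onset, onset + window], and the baseline was usable. The mean is taken
    over valid samples only.
    """
    summaries: list[SegmentSummary] = []
    for seg in segments:
        ev = seg.event
        reason = ""
        if seg.flag:
            reason = seg.flag
        elif seg.valid_fraction < 1.0 - max_invalid_fraction:
            reason = "low valid fraction"
        elif _overlaps(ev.onset_s, window_s, artifact_windows):
            reason = "artifact overlap"
        kept = reason == ""
        if kept and seg.window_valid.any():
            mean = float(np.mean(seg.normalized_pct[seg.window_valid]))
        else:
            mean = float("nan")
            if kept:
                kept, reason = False, "no valid samples"
        summaries.append(
            SegmentSummary(
                subject=subject,
                paradigm=ev.paradigm,
                epoch=ev.epoch,
                modality=ev.modality,
                signal=seg.signal,
                block_index=ev.block_index,
                onset_s=ev.onset_s,
                mean_normalized_change_pct=mean,
                valid_fraction=seg.valid_fraction,
                kept=kept,
                reason=reason,
            )
        )
    return summaries
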