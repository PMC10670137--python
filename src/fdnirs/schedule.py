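"""Stimulation schedules: theta-burst trains and single-pulse session blocks.

Theta-burst stimulation (TBS) delivers bursts of 3 pulses at 50 Hz repeated
at 5 Hz (one burst every 200 ms). The continuous variant (cTBS) runs one
uninterrupted 40 s train; the intermittent variant (iTBS) repeats a 2 s
train every 10 s for 190 s. Both deliver exactly 600 pulses.

A session wraps the TBS train with blocks of single probe pulses: 3 blocks
before and 5 after, each a randomized interleaving of 25 real and 25 sham
pulses at 6-8 s inter-stimulus intervals, with 6-10 s between blocks.
"""

from __future__ import annotations

import numpy as np

from .rng import STAGE_SCHEDULE, stage_rng
from .types import SessionSchedule, StimulusEvent

PULSES_PER_BURST = 3
INTRA_BURST_INTERVAL_S = 0.02  # 50 Hz
BURST_INTERVAL_S = 0.2  # 5 Hz

CTBS_TRAIN_S = 40.0
ITBS_TRAIN_S = 2.0
ITBS_TRAIN_PERIOD_S = 10.0
ITBS_SPAN_S = 190.0

N_PRE_BLOCKS = 3
N_POST_BLOCKS = 5
REAL_PER_BLOCK = 25
SHAM_PER_BLOCK = 25
ISI_RANGE_S = (6.0, 8.0)
IBI_RANGE_S = (6.0, 10.0)


def _burst(onset: float) -> np.ndarray:
    return onset + np.arange(PULSES_PER_BURST) * INTRA_BURST_INTERVAL_S


def make_ctbs_schedule() -> np.ndarray:
    """Pulse times (s) of one continuous theta-burst train starting at 0.

    200 burst onsets at 0, 0.2, ..., 39.8 s; 3 pulses each -> 600 pulses.
    """
    burst_onsets = np.arange(int(round(CTBS_TRAIN_S / BURST_INTERVAL_S))) * BURST_INTERVAL_S
    offsets = np.arange(PULSES_PER_BURST) * INTRA_BURST_INTERVAL_S
    return (burst_onsets[:, None] + offsets[None, :]).ravel()


def make_itbs_schedule() -> np.ndarray:
    """Pulse times (s) of one intermittent theta-burst protocol starting at 0.

    20 train onsets at 0, 10, ..., 190 s; each train holds 10 bursts of 3
    pulses -> 600 pulses.
    """
    n_trains = int(round(ITBS_SPAN_S / ITBS_TRAIN_PERIOD_S)) + 1
    train_onsets = np.arange(n_trains) * ITBS_TRAIN_PERIOD_S
    bursts_per_train = int(round(ITBS_TRAIN_S / BURST_INTERVAL_S))
    burst_offsets = np.arange(bursts_per_train) * BURST_INTERVAL_S
    pulse_offsets = np.arange(PULSES_PER_BURST) * INTRA_BURST_INTERVAL_S
    times = (
        train_onsets[:, None, None]
        + burst_offsets[None, :, None]
        + pulse_offsets[None, None, :]
    )
    return times.ravel()


def make_session_schedule(
    paradigm: str,
    subject_id: str,
    seed: int,
    *,
    start_s: float = 30.0,
    tbs_gap_s: float = 60.0,
    post_gap_s: float = 60.0,
) -> SessionSchedule:
    """Full session: pre blocks, the TBS train, post blocks.

    The first stimulus falls at ``start_s`` so a quiet lead-in exists; the
    TBS train starts ``tbs_gap_s`` after the last pre event, and the first
    post block ``post_gap_s`` after the last TBS pulse (the source protocol
    does not pin these two gaps; both are configurable).

    Deterministic for fixed ``seed``: interleavings, ISIs and IBIs all come
    from the schedule stream of the session seed.
    """
    if paradigm == "cTBS":
        tbs_base = make_ctbs_schedule()
    elif paradigm == "iTBS":
        tbs_base = make_itbs_schedule()
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected 'cTBS' or 'iTBS'")

    rng = stage_rng(seed, STAGE_SCHEDULE)
    events: list[StimulusEvent] = []
    t = float(start_s)
    tbs_pulse_times = np.empty(0)

    for block in range(N_PRE_BLOCKS + N_POST_BLOCKS):
        epoch = "pre" if block < N_PRE_BLOCKS else "post"
        if block == N_PRE_BLOCKS:
            tbs_start = events[-1].onset_s + tbs_gap_s
            tbs_pulse_times = tbs_base + tbs_start
            t = float(tbs_pulse_times[-1]) + post_gap_s
        elif block > 0:
            t = events[-1].onset_s + rng.uniform(*IBI_RANGE_S)

        labels = np.array(["real"] * REAL_PER_BLOCK + ["sham"] * SHAM_PER_BLOCK)
        rng.shuffle(labels)
        onset = t
        for i, label in enumerate(labels):
            if i > 0:
                onset = onset + rng.uniform(*ISI_RANGE_S)
            events.append(
                StimulusEvent(
                    onset_s=float(onset),
                    modality=str(label),
                    epoch=epoch,
                    paradigm=paradigm,
                    block_index=block,
                )
            )

    return SessionSchedule(
        events=events,
        tbs_pulse_times_s=tbs_pulse_times,
        paradigm=paradigm,
        subject_id=subject_id,
        seed=int(seed),
    )
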