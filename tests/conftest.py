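import numpy as np
import pandas as pd
import pytest

from fdnirs import (
    Geometry,
    HemodynamicResponseModel,
    NoiseModel,
    forward_fd,
    make_session_schedule,
    simulate_chromophores,
)


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture
def silent_noise():
    return NoiseModel.silent()


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free default-amplitude session reused across read-only tests."""
    schedule = make_session_schedule("cTBS", "s01", seed=11)
    tissue = simulate_chromophores(schedule, noise=NoiseModel.silent())
    recording = forward_fd(tissue, noise=NoiseModel.silent(), seed=11)
    return schedule, tissue, recording


def make_summary_frame(rows):
    """Minimal kept-summary frame for stats tests."""
    df = pd.DataFrame(
        rows,
        columns=[
            "subject", "paradigm", "epoch", "modality", "signal",
            "mean_normalized_change_pct",
        ],
    )
    df["kept"] = True
    return df


def simulate_event_summaries(
    n_subjects, n_events, effects, subject_sd, residual_sd, rng, signal="BV"
):
    """Event summaries drawn straight from the mixed-model generative form.

    ``effects`` maps condition (pre/cTBS/iTBS) to its true mean (%); each
    subject gets a Gaussian intercept, each event Gaussian residual noise.
    """
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0.0, subject_sd)
        for condition, mean in effects.items():
            values = mean + intercept + rng.normal(0.0, residual_sd, n_events)
            if condition == "pre":
                epoch = "pre"
                # pre events come from both paradigm sessions
                paradigms = np.where(np.arange(n_events) % 2 == 0, "cTBS", "iTBS")
            else:
                epoch = "post"
                paradigms = np.full(n_events, condition)
            for v, paradigm in zip(values, paradigms):
                rows.append({
                    "subject": f"s{s:02d}",
                    "paradigm": str(paradigm),
                    "epoch": epoch,
                    "modality": "real",
                    "signal": signal,
                    "mean_normalized_change_pct": float(v),
                })
    return make_summary_frame(rows)
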