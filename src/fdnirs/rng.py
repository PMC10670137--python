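"""Seed-stream plumbing.

One integer seed controls a whole synthetic session. Each stage draws from
its own child stream, split off the session seed with a fixed spawn key, so
adding draws to one stage never perturbs another and identical (config,
seed) pairs reproduce bit-identical sessions.
"""

from __future__ import annotations

import numpy as np

STAGE_SCHEDULE = 0
STAGE_TISSUE = 1
STAGE_OPTICS = 2


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Generator for one pipeline stage of one session."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stage),))
    return np.random.default_rng(ss)


def session_seed(root_seed: int, subject_index: int, paradigm: str) -> int:
    """Stable per-(subject, paradigm) session seed derived from a root seed."""
    code = {"cTBS": 0, "iTBS": 1}[paradigm]
    ss = np.random.SeedSequence(entropy=[int(root_seed), int(subject_index), code])
    return int(ss.generate_state(1)[0] % (2**31))
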