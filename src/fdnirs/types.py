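"""Core data containers for the frequency-domain multi-distance NIRS pipeline.

The containers mirror the physical stages of a recording session: probe
geometry, the stimulation schedule, the (ground-truth) tissue chromophore
state, the raw optical recording, and the derived chromophore time series.
All arrays are numpy; concentrations are micromolar (uM) at every public
interface, distances are cm, and phase is radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SPEED_OF_LIGHT_CM_S = 2.99792458e10

MODALITIES = ("real", "sham")
EPOCHS = ("pre", "post")
PARADIGMS = ("cTBS", "iTBS")
SIGNALS = ("BV", "HbO2", "HHb")


@dataclass(frozen=True)
class Geometry:
    """Probe geometry of a multi-distance frequency-domain instrument.

    Sources sit at several separations from one detector; the distance
    slopes of log-amplitude and phase carry the optical properties, so at
    least three distinct separations are required (two fix a line, a third
    makes the R-squared quality gate meaningful).
    """

    distances_cm: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5)
    wavelengths_nm: tuple[float, ...] = (690.0, 830.0)
    modulation_frequency_hz: float = 110e6
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_cm, dtype=float)
        if d.size < 3:
            raise ValueError("geometry needs >= 3 source-detector distances")
        if not (np.all(np.diff(d) > 0) and np.all(d > 0)):
            raise ValueError("distances must be positive and strictly increasing")
        if self.modulation_frequency_hz <= 0:
            raise ValueError("modulation_frequency_hz must be > 0")
        if self.refractive_index <= 0:
            raise ValueError("refractive_index must be > 0")
        if len(self.wavelengths_nm) < 1:
            raise ValueError("at least one wavelength required")

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.modulation_frequency_hz

    @property
    def speed_in_tissue_cm_s(self) -> float:
        """Speed of light in the medium, cm/s."""
        return SPEED_OF_LIGHT_CM_S / self.refractive_index

    @property
    def n_distances(self) -> int:
        return len(self.distances_cm)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)


@dataclass(frozen=True)
class StimulusEvent:
    """One single-pulse stimulus (real or sham) in a session."""

    onset_s: float
    modality: str
    epoch: str
    paradigm: str
    block_index: int

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"epoch must be one of {EPOCHS}")
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"paradigm must be one of {PARADIGMS}")


@dataclass
class SessionSchedule:
    """Ordered stimulus events plus the theta-burst train of one session."""

    events: list[StimulusEvent]
    tbs_pulse_times_s: np.ndarray
    paradigm: str
    subject_id: str
    seed: int

    def onsets(self, modality: str | None = None, epoch: str | None = None) -> np.ndarray:
        sel = [
            e.onset_s
            for e in self.events
            if (modality is None or e.modality == modality)
            and (epoch is None or e.epoch == epoch)
        ]
        return np.asarray(sel, dtype=float)

    @property
    def end_s(self) -> float:
        last_event = self.events[-1].onset_s if self.events else 0.0
        last_tbs = float(self.tbs_pulse_times_s[-1]) if len(self.tbs_pulse_times_s) else 0.0
        return max(last_event, last_tbs)


@dataclass
class TissueState:
    """Ground-truth chromophore concentrations on the sampling grid.

    Reduced scattering is held constant over time (one value per
    wavelength); absorption varies through the hemoglobin concentrations.
    """

    time_s: np.ndarray
    c_hbo2_uM: np.ndarray
    c_hhb_uM: np.ndarray
    musp_cm: np.ndarray  # per wavelength, 1/cm
    baseline_hbo2_uM: float
    baseline_hhb_uM: float
    fs_hz: float

    def __post_init__(self) -> None:
        if np.any(self.c_hbo2_uM <= 0) or np.any(self.c_hhb_uM <= 0):
            raise ValueError(
                "chromophore concentrations must stay positive; reduce evoked "
                "amplitudes / noise or raise the baseline"
            )

    @property
    def thb_uM(self) -> np.ndarray:
        return self.c_hbo2_uM + self.c_hhb_uM

    @property
    def baseline_thb_uM(self) -> float:
        return self.baseline_hbo2_uM + self.baseline_hhb_uM


@dataclass
class RawFDRecording:
    """Raw frequency-domain signals: DC intensity, AC amplitude, phase.

    Arrays are shaped (n_samples, n_wavelengths, n_distances).
    """

    time_s: np.ndarray
    idc: np.ndarray
    iac: np.ndarray
    phase: np.ndarray
    geometry: Geometry
    fs_hz: float = 10.4
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.idc.shape
        if self.iac.shape != shape or self.phase.shape != shape:
            raise ValueError("idc, iac and phase must share one shape")
        if shape[0] != self.time_s.shape[0]:
            raise ValueError("time axis mismatch")
        if len(shape) != 3 or shape[1] != self.geometry.n_wavelengths or shape[2] != self.geometry.n_distances:
            raise ValueError(
                "arrays must be (n_samples, n_wavelengths, n_distances) matching geometry"
            )

    @property
    def n_samples(self) -> int:
        return self.idc.shape[0]

    @property
    def artifact_windows_s(self) -> list[tuple[float, float]]:
        return list(self.meta.get("artifact_windows_s", []))


@dataclass
class ChromophoreSeries:
    """Per-sample hemoglobin concentrations with a validity mask.

    ``thb_uM`` is maintained as the exact sum of the two chromophores;
    invalid samples hold NaN. ``level_uM`` carries each signal's absolute
    concentration level (needed to express changes as percent of baseline
    once band-pass filtering has removed the mean); when absent it is taken
    as the median over valid samples.
    """

    time_s: np.ndarray
    hbo2_uM: np.ndarray
    hhb_uM: np.ndarray
    thb_uM: np.ndarray
    valid: np.ndarray
    fs_hz: float
    level_uM: dict | None = None

    @property
    def n_samples(self) -> int:
        return self.time_s.shape[0]

    def signal(self, name: str) -> np.ndarray:
        if name == "BV":
            return self.thb_uM
        if name == "HbO2":
            return self.hbo2_uM
        if name == "HHb":
            return self.hhb_uM
        raise KeyError(f"unknown signal {name!r}; expected one of {SIGNALS}")

    def level(self, name: str) -> float:
        """Absolute concentration level of a signal, uM."""
        if self.level_uM is not None and name in self.level_uM:
            return float(self.level_uM[name])
        v = self.valid.astype(bool)
        if not v.any():
            return float("nan")
        return float(np.median(self.signal(name)[v]))


@dataclass
class SlopeSeries:
    """Distance-regression slopes, intercepts and R-squared per sample/wavelength."""

    sac: np.ndarray
    sdc: np.ndarray
    sphase: np.ndarray
    cac: np.ndarray
    cdc: np.ndarray
    cphase: np.ndarray
    r2_ac: np.ndarray
    r2_dc: np.ndarray
    r2_phase: np.ndarray
    fit_valid: np.ndarray  # finite, positive intensities at every distance


@dataclass
class OpticalProperties:
    """Absorption / reduced scattering per sample and wavelength (1/cm)."""

    mua: np.ndarray
    musp: np.ndarray
    valid: np.ndarray


@dataclass
class EventSegment:
    """Baseline-normalized response of one signal to one stimulus.

    ``normalized_pct`` covers the (0, 6] s window after onset, as percent
    change of the baseline value taken at (or just before) the onset.
    """

    event: StimulusEvent
    signal: str
    normalized_pct: np.ndarray
    window_valid: np.ndarray
    baseline_uM: float
    valid_fraction: float
    flag: str = ""  # non-empty marks the segment unusable (reason)


@dataclass
class SegmentSummary:
    """Unit of statistical analysis: one event x one signal."""

    subject: str
    paradigm: str
    epoch: str
    modality: str
    signal: str
    block_index: int
    onset_s: float
    mean_normalized_change_pct: float
    valid_fraction: float
    kept: bool
    reason: str
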