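"""Synthetic tissue dynamics and the forward frequency-domain optical model.

Two stages:

1. ``simulate_chromophores`` builds ground-truth HbO2/HHb time series on
   the instrument's sampling grid: a positive baseline, condition-dependent
   evoked responses (a causal gamma-density bump added to total hemoglobin
   per stimulus), physiological oscillations (cardiac, respiratory, Mayer),
   and random-walk drift.

2. ``forward_fd`` turns a tissue state into raw multi-distance
   frequency-domain signals. At each sample and wavelength the absorption
   coefficient follows from the chromophore concentrations; with reduced
   scattering it fixes the complex attenuation kappa = k_r + i*k_i of a
   photon-density wave through

       k_r^2 - k_i^2 = 3 * mua * (mua + musp)
       2 * k_r * k_i = 3 * (mua + musp) * omega / v

   and the emitted signals decay as IAC(r) = A exp(-k_r r) / r^2 with phase
   k_i r + phi0, so ln(r^2 IAC) and phase are exactly linear in distance
   and the slope pair (-k_r, k_i) is exactly invertible. Optical noise and
   labelled motion artifacts are applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .extinction import ExtinctionTable
from .rng import STAGE_OPTICS, STAGE_TISSUE, stage_rng
from .types import Geometry, RawFDRecording, SessionSchedule, TissueState

DEFAULT_FS_HZ = 10.4
DEFAULT_BASELINE_UM = (42.0, 18.0)  # HbO2, HHb: tHb 60 uM at 70% saturation
DEFAULT_MUSP_CM = (8.0, 7.0)  # per wavelength (690, 830 nm)

# forward-model instrument constants (arbitrary units / radians)
SOURCE_AMPLITUDE_AC = 1.0e5
SOURCE_AMPLITUDE_DC = 2.0e5
PHASE_OFFSET_RAD = 0.1


def default_amplitudes() -> dict[tuple[str, str, str], float]:
    """Peak evoked tHb change, % of baseline, keyed (modality, epoch, paradigm).

    Only real probe pulses after the inhibitory (cTBS) train evoke a
    response; sham pulses and everything around the excitatory (iTBS) train
    evoke none. The 14% peak matches the scale of the group difference the
    pipeline is meant to resolve.
    """
    return {("real", "post", "cTBS"): 14.0}


@dataclass
class HemodynamicResponseModel:
    """Condition-dependent evoked response: a causal gamma-density bump.

    The kernel is zero for t < 0, peaks ``peak_latency_s`` after the
    stimulus with spread ``dispersion_s``, and is scaled to unit peak so an
    amplitude of a% produces a peak tHb excursion of a% of baseline. The
    evoked tHb change is split ``hbo2_share`` : (1 - share) between HbO2
    and HHb.
    """

    amplitudes: dict = field(default_factory=default_amplitudes)
    peak_latency_s: float = 3.5
    dispersion_s: float = 1.5
    hbo2_share: float = 0.8

    def amplitude(self, modality: str, epoch: str, paradigm: str) -> float:
        return float(self.amplitudes.get((modality, epoch, paradigm), 0.0))

    def _shape_scale(self) -> tuple[float, float]:
        # gamma density with mode = peak latency, sd = dispersion
        ratio = self.peak_latency_s / self.dispersion_s
        sqrt_k = (ratio + np.hypot(ratio, 2.0)) / 2.0
        k = sqrt_k**2
        theta = self.dispersion_s / sqrt_k
        return k, theta

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak evoked kernel evaluated at times t (s); 0 for t < 0."""
        k, theta = self._shape_scale()
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        mode = (k - 1.0) * theta
        log_peak = (k - 1.0) * np.log(mode) - mode / theta
        out[pos] = np.exp((k - 1.0) * np.log(tp) - tp / theta - log_peak)
        return out

    @property
    def support_s(self) -> float:
        """Time after which the kernel is negligible."""
        return self.peak_latency_s + 10.0 * self.dispersion_s

    def to_dict(self) -> dict:
        return {
            "amplitudes_pct": {"|".join(k): v for k, v in self.amplitudes.items()},
            "peak_latency_s": self.peak_latency_s,
            "dispersion_s": self.dispersion_s,
            "hbo2_share": self.hbo2_share,
        }


@dataclass
class NoiseModel:
    """Physiological + instrument noise. All-zero fields give a clean recording.

    Oscillation entries are (frequency Hz, amplitude as % of baseline tHb).
    ``drift_sd_pct`` is the per-sample standard deviation of a random walk
    in % of baseline tHb. ``optical_rel_sd`` is the relative SD of white
    noise multiplied onto IAC and IDC; ``phase_sd_rad`` is additive on
    phase. Motion artifacts arrive at ``artifact_rate_per_min`` and scale
    intensities by channel-dependent factors around
    ``artifact_magnitude`` for ``artifact_duration_s`` — breaking the
    distance linearity so the R-squared gate can see them — and every
    window is recorded as a ground-truth label.
    """

    cardiac: tuple[float, float] = (1.1, 1.0)
    respiratory: tuple[float, float] = (0.25, 0.5)
    mayer: tuple[float, float] = (0.1, 0.5)
    drift_sd_pct: float = 0.01
    optical_rel_sd: float = 0.005
    phase_sd_rad: float = 0.001
    artifact_rate_per_min: float = 0.2
    artifact_magnitude: float = 2.0
    artifact_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("drift_sd_pct", "optical_rel_sd", "phase_sd_rad",
                     "artifact_rate_per_min", "artifact_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cardiac", "respiratory", "mayer"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} amplitude must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(
            cardiac=(1.1, 0.0),
            respiratory=(0.25, 0.0),
            mayer=(0.1, 0.0),
            drift_sd_pct=0.0,
            optical_rel_sd=0.0,
            phase_sd_rad=0.0,
            artifact_rate_per_min=0.0,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_chromophores(
    schedule: SessionSchedule,
    hrf: HemodynamicResponseModel | None = None,
    noise: NoiseModel | None = None,
    baseline_uM: tuple[float, float] = DEFAULT_BASELINE_UM,
    seed: int | None = None,
    *,
    fs_hz: float = DEFAULT_FS_HZ,
    musp_cm: tuple[float, ...] = DEFAULT_MUSP_CM,
    tail_s: float = 30.0,
) -> TissueState:
    """Ground-truth chromophore dynamics for one session.

    C(t) = baseline * (1 + evoked(t) + oscillations(t) + drift(t)), with the
    evoked fraction summing each event's amplitude-scaled kernel. The
    physiological terms ride on total hemoglobin and are split between the
    chromophores with the response model's HbO2 share.
    """
    hrf = hrf if hrf is not None else HemodynamicResponseModel()
    noise = noise if noise is not None else NoiseModel()
    b_hbo2, b_hhb = (float(baseline_uM[0]), float(baseline_uM[1]))
    if b_hbo2 <= 0 or b_hhb <= 0:
        raise ValueError("baseline concentrations must be > 0")
    rng = stage_rng(schedule.seed if seed is None else seed, STAGE_TISSUE)

    duration = schedule.end_s + tail_s
    n = int(round(duration * fs_hz))
    t = np.arange(n) / fs_hz
    thb0 = b_hbo2 + b_hhb

    frac = np.zeros(n)
    support = hrf.support_s
    for ev in schedule.events:
        a = hrf.amplitude(ev.modality, ev.epoch, ev.paradigm)
        if a == 0.0:
            continue
        i0 = int(np.searchsorted(t, ev.onset_s))
        i1 = min(n, int(np.ceil((ev.onset_s + support) * fs_hz)) + 1)
        frac[i0:i1] += (a / 100.0) * hrf.kernel(t[i0:i1] - ev.onset_s)

    for f_hz, amp_pct in (noise.cardiac, noise.respiratory, noise.mayer):
        if amp_pct > 0:
            phi = rng.uniform(0.0, 2.0 * np.pi)
            frac += (amp_pct / 100.0) * np.sin(2.0 * np.pi * f_hz * t + phi)
    if noise.drift_sd_pct > 0:
        frac += np.cumsum(rng.normal(0.0, noise.drift_sd_pct / 100.0, n))

    delta = thb0 * frac  # uM change in tHb
    c_hbo2 = b_hbo2 + hrf.hbo2_share * delta
    c_hhb = b_hhb + (1.0 - hrf.hbo2_share) * delta
    if n and (c_hbo2.min() <= 0 or c_hhb.min() <= 0):
        raise ValueError(
            "simulated concentrations became non-positive "
            f"(min HbO2 {c_hbo2.min():.3g} uM, min HHb {c_hhb.min():.3g} uM); "
            "lower the evoked amplitudes / noise or raise the baseline"
        )

    return TissueState(
        time_s=t,
        c_hbo2_uM=c_hbo2,
        c_hhb_uM=c_hhb,
        musp_cm=np.asarray(musp_cm, dtype=float),
        baseline_hbo2_uM=b_hbo2,
        baseline_hhb_uM=b_hhb,
        fs_hz=fs_hz,
    )


def photon_density_wave_attenuation(mua, musp, omega: float, v: float):
    """Real/imaginary attenuation (k_r, k_i) of the diffuse photon-density wave.

    Solves k_r^2 - k_i^2 = 3 mua (mua + musp), 2 k_r k_i = 3 (mua + musp)
    omega / v via the principal complex square root.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    alpha = 3.0 * mua * (mua + musp)
    beta = 3.0 * (mua + musp) * omega / v
    kappa = np.sqrt(alpha + 1j * beta)
    return kappa.real, kappa.imag


def forward_fd(
    tissue: TissueState,
    geometry: Geometry | None = None,
    extinction: ExtinctionTable | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    meta: dict | None = None,
) -> RawFDRecording:
    """Raw frequency-domain signals for a tissue state.

    Noise-free output is exactly linear in distance for ln(r^2 IAC),
    ln(r^2 IDC) and phase. Motion-artifact windows are returned as
    ground-truth labels in ``meta['artifact_windows_s']``.
    """
    geometry = geometry if geometry is not None else Geometry()
    extinction = extinction if extinction is not None else ExtinctionTable()
    noise = noise if noise is not None else NoiseModel()
    if len(tissue.musp_cm) != geometry.n_wavelengths:
        raise ValueError("tissue.musp_cm must hold one value per geometry wavelength")

    mua = extinction.mua_from_concentrations(
        geometry.wavelengths_nm, tissue.c_hbo2_uM, tissue.c_hhb_uM
    )  # (n, nw)
    musp = np.broadcast_to(tissue.musp_cm, mua.shape)
    if mua.size and (np.min(mua) <= 0 or np.min(musp) <= 0):
        raise ValueError("mua and musp must be positive everywhere")

    kr, ki = photon_density_wave_attenuation(
        mua, musp, geometry.omega, geometry.speed_in_tissue_cm_s
    )
    kappa0 = np.sqrt(3.0 * mua * (mua + musp))

    r = np.asarray(geometry.distances_cm)  # (nd,)
    iac = SOURCE_AMPLITUDE_AC * np.exp(-kr[..., None] * r) / r**2
    idc = SOURCE_AMPLITUDE_DC * np.exp(-kappa0[..., None] * r) / r**2
    phase = ki[..., None] * r + PHASE_OFFSET_RAD

    rng = stage_rng(seed, STAGE_OPTICS)
    n = tissue.time_s.shape[0]
    if noise.optical_rel_sd > 0:
        iac = iac * (1.0 + rng.normal(0.0, noise.optical_rel_sd, iac.shape))
        idc = idc * (1.0 + rng.normal(0.0, noise.optical_rel_sd, idc.shape))
    if noise.phase_sd_rad > 0:
        phase = phase + rng.normal(0.0, noise.phase_sd_rad, phase.shape)

    artifact_windows: list[tuple[float, float]] = []
    if noise.artifact_rate_per_min > 0 and n:
        duration_min = n / tissue.fs_hz / 60.0
        n_artifacts = rng.poisson(noise.artifact_rate_per_min * duration_min)
        for _ in range(int(n_artifacts)):
            t0 = rng.uniform(0.0, n / tissue.fs_hz)
            t1 = t0 + noise.artifact_duration_s
            i0, i1 = int(t0 * tissue.fs_hz), min(n, int(np.ceil(t1 * tissue.fs_hz)))
            if i0 >= n:
                continue
            # channel-dependent excursions break the distance linearity
            shape = (geometry.n_wavelengths, geometry.n_distances)
            log_m = np.log(noise.artifact_magnitude) if noise.artifact_magnitude > 0 else 0.0
            factors = np.exp(log_m * (1.0 + 0.5 * rng.standard_normal(shape)))
            iac[i0:i1] *= factors
            idc[i0:i1] *= factors
            phase[i0:i1] += 0.2 * log_m * rng.standard_normal(shape)
            artifact_windows.append((float(t0), float(min(t1, n / tissue.fs_hz))))

    full_meta = dict(meta or {})
    full_meta["artifact_windows_s"] = artifact_windows
    return RawFDRecording(
        time_s=tissue.time_s.copy(),
        idc=idc,
        iac=iac,
        phase=phase,
        geometry=geometry,
        fs_hz=tissue.fs_hz,
        meta=full_meta,
    )
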