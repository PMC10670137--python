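"""Multi-distance slope fits and inversion to optical / hemoglobin values.

At every sample and wavelength, ln(r^2 IAC), ln(r^2 IDC) and phase are
regressed on source-detector distance r. The AC and phase slopes (S_AC,
S_phase) determine the tissue absorption and reduced scattering
coefficients in closed form: with a = |S_AC|,

    mua  = (omega / 2v) * (a / S_phase - S_phase / a)
    musp = (a^2 - S_phase^2) / (3 mua) - mua

Two-wavelength absorption then yields HbO2 and HHb by a 2x2 linear solve,
and total hemoglobin (the blood-volume proxy) is their exact sum. Samples
whose amplitude or phase fit has R^2 below threshold (default 0.97) at
either wavelength are discarded, as are samples with non-positive
intensities or slopes outside the physical region (S_AC < 0 < S_phase,
|S_AC| > S_phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extinction import LN10, ExtinctionTable
from .types import (
    ChromophoreSeries,
    Geometry,
    OpticalProperties,
    RawFDRecording,
    SlopeSeries,
)

DEFAULT_R2_THRESHOLD = 0.97


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line y = slope*x + intercept along the last axis of y.

    Returns (slope, intercept, r2). A zero-variance response gets slope 0,
    R^2 = 0 by convention (the textbook formula is 0/0; treating flat lines
    as "no fit" makes the quality gate reject dead channels).
    """
    xm = x.mean()
    xd = x - xm
    sxx = float(np.dot(xd, xd))
    ym = y.mean(axis=-1, keepdims=True)
    yd = y - ym
    slope = (yd @ xd) / sxx
    intercept = ym[..., 0] - slope * xm
    sstot = np.sum(yd * yd, axis=-1)
    ssres = sstot - slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sstot > 0, 1.0 - ssres / np.where(sstot > 0, sstot, 1.0), 0.0)
    return slope, intercept, np.clip(r2, 0.0, 1.0)


def fit_multidistance(
    iac: np.ndarray,
    idc: np.ndarray,
    phase: np.ndarray,
    distances_cm,
) -> SlopeSeries:
    """Distance-regressions of one or many samples.

    Inputs are (..., n_distances); a single sample may be passed as 1-D
    arrays. Phase is unwrapped across distances before fitting. Samples
    with a non-positive or non-finite intensity at any distance are marked
    invalid (NaN results, no exception).
    """
    r = np.asarray(distances_cm, dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 distances for a gated linear fit")
    iac = np.asarray(iac, dtype=float)
    idc = np.asarray(idc, dtype=float)
    phase = np.asarray(phase, dtype=float)

    ok = (
        np.all(iac > 0, axis=-1)
        & np.all(idc > 0, axis=-1)
        & np.all(np.isfinite(iac), axis=-1)
        & np.all(np.isfinite(idc), axis=-1)
        & np.all(np.isfinite(phase), axis=-1)
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        y_ac = np.log(r**2 * np.where(iac > 0, iac, np.nan))
        y_dc = np.log(r**2 * np.where(idc > 0, idc, np.nan))
    y_ph = np.unwrap(phase, axis=-1)

    sac, cac, r2_ac = _ols_line(r, np.where(ok[..., None], y_ac, 0.0))
    sdc, cdc, r2_dc = _ols_line(r, np.where(ok[..., None], y_dc, 0.0))
    sph, cph, r2_ph = _ols_line(r, np.where(ok[..., None], y_ph, 0.0))

    bad = ~ok
    sac, cac, sdc, cdc, sph, cph = (
        np.where(bad, np.nan, arr) for arr in (sac, cac, sdc, cdc, sph, cph)
    )
    r2_ac, r2_dc, r2_ph = (np.where(bad, 0.0, arr) for arr in (r2_ac, r2_dc, r2_ph))

    return SlopeSeries(
        sac=sac, sdc=sdc, sphase=sph,
        cac=cac, cdc=cdc, cphase=cph,
        r2_ac=r2_ac, r2_dc=r2_dc, r2_phase=r2_ph,
        fit_valid=np.asarray(ok),
    )


def invert_optical(sac, sphase, omega: float, v: float):
    """Absorption and reduced scattering (1/cm) from the AC/phase slope pair.

    Valid only for S_AC < 0 < S_phase with |S_AC| > S_phase; outside that
    region both outputs are NaN (scalar inputs return floats).
    """
    sac = np.asarray(sac, dtype=float)
    sphase = np.asarray(sphase, dtype=float)
    a = -sac
    valid = (a > 0) & (sphase > 0) & (a > sphase)
    with np.errstate(invalid="ignore", divide="ignore"):
        mua = (omega / (2.0 * v)) * (a / sphase - sphase / a)
        musp = (a**2 - sphase**2) / (3.0 * mua) - mua
    mua = np.where(valid, mua, np.nan)
    musp = np.where(valid, musp, np.nan)
    if mua.ndim == 0:
        return float(mua), float(musp)
    return mua, musp


def solve_chromophores(mua_by_wavelength: np.ndarray, extinction: ExtinctionTable,
                       wavelengths_nm=None):
    """HbO2 and HHb concentrations (uM) from two-wavelength absorption.

    Solves mua(lambda) = ln(10) * [eps_HbO2, eps_HHb](lambda) . C for C in
    mM and reports uM. ``mua_by_wavelength`` is (..., 2) ordered like the
    extinction table's wavelengths (or ``wavelengths_nm`` if given).
    """
    wl = wavelengths_nm if wavelengths_nm is not None else extinction.wavelengths_nm
    e = extinction.submatrix(wl)
    if e.shape[0] != 2:
        raise ValueError("chromophore solve needs exactly two wavelengths")
    e_inv = np.linalg.inv(e)
    mua = np.asarray(mua_by_wavelength, dtype=float)
    c_mM = (mua @ e_inv.T) / LN10
    c_uM = c_mM * 1000.0
    return c_uM[..., 0], c_uM[..., 1]


def qc_mask(slopes: SlopeSeries, threshold: float = DEFAULT_R2_THRESHOLD) -> np.ndarray:
    """Per-sample validity: amplitude AND phase fits reach R^2 >= threshold
    at every wavelength (the DC fit is reported but not gated)."""
    per_wavelength = (slopes.r2_ac >= threshold) & (slopes.r2_phase >= threshold)
    return np.all(per_wavelength & slopes.fit_valid, axis=-1)


def invert_recording(
    recording: RawFDRecording,
    extinction: ExtinctionTable | None = None,
    threshold: float = DEFAULT_R2_THRESHOLD,
):
    """Full per-sample pipeline: fit -> gate -> invert -> chromophore solve.

    Returns (ChromophoreSeries, SlopeSeries, OpticalProperties). Invalid
    samples carry NaN concentrations and False in the validity mask.
    """
    extinction = extinction if extinction is not None else ExtinctionTable()
    geom = recording.geometry
    slopes = fit_multidistance(
        recording.iac, recording.idc, recording.phase, geom.distances_cm
    )
    mua, musp = invert_optical(
        slopes.sac, slopes.sphase, geom.omega, geom.speed_in_tissue_cm_s
    )
    optics_valid = np.isfinite(mua) & np.isfinite(musp) & (mua > 0) & (musp > 0)
    optics = OpticalProperties(mua=mua, musp=musp, valid=optics_valid)

    valid = qc_mask(slopes, threshold) & np.all(optics_valid, axis=-1)
    n = recording.n_samples
    hbo2 = np.full(n, np.nan)
    hhb = np.full(n, np.nan)
    if n and valid.any():
        c1, c2 = solve_chromophores(
            mua[valid], extinction, wavelengths_nm=geom.wavelengths_nm
        )
        hbo2[valid] = c1
        hhb[valid] = c2
    series = ChromophoreSeries(
        time_s=recording.time_s.copy(),
        hbo2_uM=hbo2,
        hhb_uM=hhb,
        thb_uM=hbo2 + hhb,
        valid=valid,
        fs_hz=recording.fs_hz,
    )
    return series, slopes, optics


@dataclass
class FDInversionResults:
    """Results of fitting the multi-distance model to a raw recording."""

    chromophores: ChromophoreSeries
    slopes: SlopeSeries
    optical: OpticalProperties
    r2_threshold: float
    geometry: Geometry

    @property
    def valid_fraction(self) -> float:
        n = self.chromophores.n_samples
        return float(self.chromophores.valid.mean()) if n else float("nan")

    def summary(self) -> str:
        c = self.chromophores
        lines = [
            "Frequency-domain multi-distance inversion",
            "=" * 45,
            f"samples                {c.n_samples}",
            f"valid samples          {int(c.valid.sum())} ({100 * self.valid_fraction:.2f}%)",
            f"R^2 gate (AC & phase)  >= {self.r2_threshold}",
        ]
        v = c.valid
        if v.any():
            for i, wl in enumerate(self.geometry.wavelengths_nm):
                lines.append(
                    f"{wl:g} nm: mua {np.nanmean(self.optical.mua[v, i]):.4f} 1/cm, "
                    f"musp {np.nanmean(self.optical.musp[v, i]):.3f} 1/cm"
                )
            lines.append(
                f"mean HbO2 {np.nanmean(c.hbo2_uM[v]):.2f} uM, "
                f"HHb {np.nanmean(c.hhb_uM[v]):.2f} uM, "
                f"tHb {np.nanmean(c.thb_uM[v]):.2f} uM"
            )
        return "\n".join(lines)


class FDMultiDistanceModel:
    """Statsmodels-style wrapper: raw recording in, fitted results out.

    >>> res = FDMultiDistanceModel(recording).fit()
    >>> res.chromophores.thb_uM
    """

    def __init__(
        self,
        recording: RawFDRecording,
        extinction: ExtinctionTable | None = None,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
    ):
        self.recording = recording
        self.extinction = extinction if extinction is not None else ExtinctionTable()
        self.r2_threshold = float(r2_threshold)

    def fit(self) -> FDInversionResults:
        series, slopes, optics = invert_recording(
            self.recording, self.extinction, self.r2_threshold
        )
        return FDInversionResults(
            chromophores=series,
            slopes=slopes,
            optical=optics,
            r2_threshold=self.r2_threshold,
            geometry=self.recording.geometry,
        )
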