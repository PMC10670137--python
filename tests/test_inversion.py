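import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from fdnirs import (
    ExtinctionTable,
    FDMultiDistanceModel,
    Geometry,
    NoiseModel,
    fit_multidistance,
    invert_optical,
    invert_recording,
    qc_mask,
    solve_chromophores,
)
from fdnirs.extinction import LN10
from fdnirs.simulate import photon_density_wave_attenuation
from fdnirs.types import RawFDRecording

GEOM = Geometry()
R = np.asarray(GEOM.distances_cm)


def synth_sample(mua, musp, amp=1e5, phase0=0.1):
    kr, ki = photon_density_wave_attenuation(mua, musp, GEOM.omega,
                                             GEOM.speed_in_tissue_cm_s)
    iac = amp * np.exp(-kr * R) / R**2
    idc = amp * np.exp(-np.sqrt(3 * mua * (mua + musp)) * R) / R**2
    phase = ki * R + phase0
    return iac, idc, phase


class TestFitMultidistance:
    def test_exact_linearity_of_synthetic_sample(self):
        iac, idc, phase = synth_sample(0.1, 10.0)
        s = fit_multidistance(iac, idc, phase, R)
        assert s.r2_ac == pytest.approx(1.0, abs=1e-12)
        assert s.r2_phase == pytest.approx(1.0, abs=1e-12)

    def test_flat_phase_has_zero_slope_and_zero_r2(self):
        iac, idc, _ = synth_sample(0.1, 10.0)
        s = fit_multidistance(iac, idc, np.full(4, 0.3), R)
        assert s.sphase == pytest.approx(0.0)
        assert s.r2_phase == 0.0

    def test_hand_computed_fixture_with_balanced_residuals(self):
        # ln(r^2 IAC) = -2 r + 1 plus residuals (+d, -d, -d, +d): the
        # residual pattern is orthogonal to the centered distances, so the
        # slope stays exactly -2 and R^2 = 1 - 4 d^2 / SS_tot.
        d = 0.01
        y = -2.0 * R + 1.0 + np.array([d, -d, -d, d])
        iac = np.exp(y) / R**2
        s = fit_multidistance(iac, iac, np.zeros(4) + 0.1 * R, R)
        sstot = np.sum((y - y.mean()) ** 2)
        assert s.sac == pytest.approx(-2.0, abs=1e-12)
        assert s.cac == pytest.approx(1.0, abs=1e-12)
        assert s.r2_ac == pytest.approx(1.0 - 4 * d**2 / sstot, abs=1e-12)
        # independent oracle: generic least squares
        coef, res, *_ = np.linalg.lstsq(np.vstack([R, np.ones(4)]).T, y, rcond=None)
        assert s.sac == pytest.approx(coef[0])
        assert s.r2_ac == pytest.approx(1.0 - res[0] / sstot)

    def test_nonpositive_intensity_marks_sample_invalid(self):
        iac, idc, phase = synth_sample(0.1, 10.0)
        iac_bad = iac.copy()
        iac_bad[2] = -1.0
        s = fit_multidistance(iac_bad, idc, phase, R)
        assert not s.fit_valid
        assert np.isnan(s.sac)
        assert s.r2_ac == 0.0

    def test_phase_unwrapping_across_distances(self):
        iac, idc, phase = synth_sample(0.3, 12.0, phase0=3.0)
        wrapped = np.angle(np.exp(1j * phase))  # fold into (-pi, pi]
        s_ref = fit_multidistance(iac, idc, phase, R)
        s_wrapped = fit_multidistance(iac, idc, wrapped, R)
        assert s_wrapped.sphase == pytest.approx(s_ref.sphase, rel=1e-12)

    def test_fewer_than_three_distances_rejected(self):
        with pytest.raises(ValueError, match="3 distances"):
            fit_multidistance(np.ones(2), np.ones(2), np.ones(2), [2.0, 3.0])


class TestInvertOptical:
    def test_round_trip_at_reference_point(self):
        iac, idc, phase = synth_sample(0.1, 10.0)
        s = fit_multidistance(iac, idc, phase, R)
        mua, musp = invert_optical(s.sac, s.sphase, GEOM.omega,
                                   GEOM.speed_in_tissue_cm_s)
        assert abs(mua - 0.1) / 0.1 <= 1e-9
        assert abs(musp - 10.0) / 10.0 <= 1e-9

    def test_closed_form_attenuation_matches_numerical_root(self):
        mua, musp = 0.1, 10.0
        om, v = GEOM.omega, GEOM.speed_in_tissue_cm_s

        def equations(k):
            kr, ki = k
            return [kr**2 - ki**2 - 3 * mua * (mua + musp),
                    2 * kr * ki - 3 * (mua + musp) * om / v]

        kr_num, ki_num = fsolve(equations, [1.0, 0.1])
        kr, ki = photon_density_wave_attenuation(mua, musp, om, v)
        assert kr == pytest.approx(kr_num, rel=1e-9)
        assert ki == pytest.approx(ki_num, rel=1e-9)

    def test_validity_boundary_mua_goes_to_zero(self):
        om, v = GEOM.omega, GEOM.speed_in_tissue_cm_s
        sphase = 0.3
        for eps in (1e-4, 1e-6, 1e-8):
            mua, _ = invert_optical(-(sphase * (1 + eps)), sphase, om, v)
            assert 0 < mua < 1e-2
        mua_bad, musp_bad = invert_optical(-sphase, sphase, om, v)
        assert np.isnan(mua_bad) and np.isnan(musp_bad)

    def test_depends_only_on_omega_over_v(self):
        mua_a, musp_a = invert_optical(-1.8, 0.28, GEOM.omega,
                                       GEOM.speed_in_tissue_cm_s)
        mua_b, musp_b = invert_optical(-1.8, 0.28, GEOM.omega * 3.0,
                                       GEOM.speed_in_tissue_cm_s * 3.0)
        assert mua_a == pytest.approx(mua_b, rel=1e-12)
        assert musp_a == pytest.approx(musp_b, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        mua=st.floats(0.01, 0.5),
        musp=st.floats(5.0, 20.0),
    )
    def test_round_trip_property(self, mua, musp):
        kr, ki = photon_density_wave_attenuation(
            mua, musp, GEOM.omega, GEOM.speed_in_tissue_cm_s
        )
        mua_hat, musp_hat = invert_optical(-kr, ki, GEOM.omega,
                                           GEOM.speed_in_tissue_cm_s)
        assert abs(mua_hat - mua) / mua <= 1e-8
        assert abs(musp_hat - musp) / musp <= 1e-8

    def test_mua_monotone_in_slope_magnitude(self):
        mua_grid = np.linspace(0.02, 0.5, 50)
        kr, ki = photon_density_wave_attenuation(
            mua_grid, 10.0, GEOM.omega, GEOM.speed_in_tissue_cm_s
        )
        assert np.all(np.diff(kr) > 0)  # |S_AC| grows with absorption
        assert np.all(np.diff(kr / ki) > 0)  # and so does the slope ratio


class TestSolveChromophores:
    def test_zero_absorption_gives_zero_concentrations(self):
        ext = ExtinctionTable()
        c1, c2 = solve_chromophores(np.zeros(2), ext)
        assert c1 == 0.0 and c2 == 0.0

    def test_exact_recovery_of_known_concentrations(self):
        ext = ExtinctionTable()
        c_true = np.array([42.0, 18.0])  # uM
        mua = LN10 * ext.matrix @ (c_true / 1000.0)
        hbo2, hhb = solve_chromophores(mua, ext)
        assert hbo2 == pytest.approx(42.0, rel=1e-12)
        assert hhb == pytest.approx(18.0, rel=1e-12)

    def test_wavelength_permutation_invariance(self):
        ext = ExtinctionTable()
        mua = np.array([0.11, 0.12])
        a = solve_chromophores(mua, ext, wavelengths_nm=(690.0, 830.0))
        b = solve_chromophores(mua[::-1], ext, wavelengths_nm=(830.0, 690.0))
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_singular_table_rejected_at_construction(self):
        with pytest.raises(ValueError, match="singular"):
            ExtinctionTable({690.0: {"HbO2": 1.0, "HHb": 2.0},
                             830.0: {"HbO2": 2.0, "HHb": 4.0}})


class TestQCMask:
    def _slopes_with_r2(self, r2_ac, r2_phase):
        iac, idc, phase = synth_sample(0.1, 10.0)
        s = fit_multidistance(
            np.tile(iac, (1, 2, 1)), np.tile(idc, (1, 2, 1)),
            np.tile(phase, (1, 2, 1)), R,
        )
        s.r2_ac = np.full((1, 2), r2_ac)
        s.r2_phase = np.full((1, 2), r2_phase)
        return s

    def test_phase_failure_invalidates_even_with_good_amplitude(self):
        s = self._slopes_with_r2(0.98, 0.95)
        assert not qc_mask(s, 0.97)[0]

    def test_perfect_fits_pass(self):
        s = self._slopes_with_r2(1.0, 1.0)
        assert qc_mask(s, 0.97)[0]

    def test_zero_threshold_is_vacuous(self):
        s = self._slopes_with_r2(0.5, 0.1)
        assert qc_mask(s, 0.0)[0]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_gate_monotone_in_threshold(self, t_low, t_high):
        t_low, t_high = sorted((t_low, t_high))
        s = self._slopes_with_r2(0.9, 0.99)
        assert not (qc_mask(s, t_high)[0] and not qc_mask(s, t_low)[0])


class TestInvertRecording:
    def test_noise_free_session_round_trip(self, clean_session):
        _, tissue, recording = clean_session
        series, slopes, optics = invert_recording(recording)
        assert series.valid.all()
        assert np.nanmax(np.abs(series.hbo2_uM - tissue.c_hbo2_uM)) <= 1e-6
        assert np.nanmax(np.abs(series.hhb_uM - tissue.c_hhb_uM)) <= 1e-6

    def test_thb_is_exact_sum_on_valid_samples(self, clean_session):
        _, _, recording = clean_session
        series, _, _ = invert_recording(recording)
        v = series.valid
        assert np.array_equal(series.thb_uM[v],
                              series.hbo2_uM[v] + series.hhb_uM[v])

    def test_artifact_window_fails_the_gate(self, clean_session, silent_noise):
        from fdnirs import forward_fd, simulate_chromophores, make_session_schedule
        schedule = make_session_schedule("cTBS", "a01", seed=21)
        tissue = simulate_chromophores(schedule, noise=silent_noise)
        noisy = NoiseModel(artifact_rate_per_min=1.0, optical_rel_sd=0.005,
                           phase_sd_rad=0.001)
        rec = forward_fd(tissue, noise=noisy, seed=21)
        assert rec.artifact_windows_s
        series, _, _ = invert_recording(rec)
        fs = rec.fs_hz
        inside = np.zeros(rec.n_samples, dtype=bool)
        for t0, t1 in rec.artifact_windows_s:
            inside[int(t0 * fs): int(np.ceil(t1 * fs))] = True
        # the corrupted stretches must be predominantly rejected
        assert series.valid[inside].mean() < 0.1
        assert series.valid[~inside].mean() > 0.95

    def test_empty_recording_yields_empty_series(self, geometry):
        empty = RawFDRecording(
            time_s=np.empty(0),
            idc=np.empty((0, 2, 4)), iac=np.empty((0, 2, 4)),
            phase=np.empty((0, 2, 4)),
            geometry=geometry,
        )
        series, slopes, optics = invert_recording(empty)
        assert series.n_samples == 0

    def test_model_results_summary_reports_validity(self, clean_session):
        _, _, recording = clean_session
        res = FDMultiDistanceModel(recording).fit()
        assert res.valid_fraction == 1.0
        text = res.summary()
        assert "100.00%" in text and "mua" in text
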