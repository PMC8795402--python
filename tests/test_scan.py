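"""Tests for scan patterns, exact timing, waveforms and the ETL transient."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ntcsim import scan
from ntcsim.optics import EtlModel
from ntcsim.scan import ScanRegion, ZProfile


# ---------------------------------------------------------------------------
# timing


@pytest.mark.parametrize(
    "n_lines,period_ms,printed",
    [
        (256, 1.0, 3.91),
        (128, 1.0, 7.81),
        (170, 1.0, 5.88),
        (64, 1.0, 15.6),
        (1024, 2.0, 0.49),
        (512, 2.0, 0.98),
    ],
)
def test_activity_scan_rates_match_printed_values(n_lines, period_ms, printed):
    r = scan.timing_report(scan.build_raster(n_lines, n_lines, period_ms))
    digits = 2 if printed < 10 else 1
    assert round(r.frame_rate_hz, digits) == printed
    # exact rational path agrees with the float path
    assert float(r.exact_frame_rate) == pytest.approx(r.frame_rate_hz, rel=1e-12)


def test_exact_rational_rates():
    r = scan.timing_report(scan.build_raster(256, 256, 1.0))
    assert r.exact_frame_rate == Fraction(1000, 256)
    # integer-microsecond recomputation matches to 1e-12 relative
    us = 256 * 1000
    assert abs(1e6 / us - r.frame_rate_hz) <= 1e-12 * r.frame_rate_hz


def test_single_line_cycle():
    r = scan.timing_report(scan.build_raster(1, 16, 1.0))
    assert r.cycle_duration_ms == 1.0


def test_multiplane_volume_rate():
    planes = [i * 15.0 for i in range(6)]
    pat = scan.build_raster(6 * 170, 340, 1.0, z_profile=ZProfile.multiplane(planes))
    r = scan.timing_report(pat)
    assert round(r.per_plane_rate_hz, 2) == 0.98
    assert r.per_plane_rate_hz == r.frame_rate_hz  # each plane once per volume


def test_random_access_cycle_arithmetic():
    regions = [ScanRegion(128, 128, 1.0, origin_um=(-500, 0)), ScanRegion(128, 128, 1.0, origin_um=(500, 0))]
    pat = scan.build_random_access(regions, transition_lines=2)
    r = scan.timing_report(pat)
    assert r.cycle_duration_ms == 128 + 2 + 128 + 2
    assert r.transition_duration_ms == 2.0
    # the printed convention excludes the blanked transitions
    assert r.active_rate_hz == pytest.approx(1000.0 / 256.0)


def test_single_region_random_access_degenerates_to_raster():
    region = ScanRegion(64, 64, 1.0)
    pat = scan.build_random_access([region])
    assert scan.timing_report(pat).cycle_duration_ms == scan.timing_report(
        scan.build_raster(64, 64, 1.0)
    ).cycle_duration_ms


def test_extent_beyond_fov_rejected():
    with pytest.raises(ValueError, match="field of view"):
        scan.build_raster(64, 64, 1.0, extent_um=(4000.0, 4000.0), fov_limit_um=3500.0)
    with pytest.raises(ValueError, match="outside"):
        scan.build_random_access(
            [ScanRegion(64, 64, 1.0, origin_um=(0, 0)), ScanRegion(64, 64, 1.0, origin_um=(3000, 0))],
            fov_limit_um=3500.0,
        )


def test_eye_brain_split_plane_structure():
    """Two regions with distinct staircase z-offsets build cleanly."""
    eye = ScanRegion(64, 128, 1.0, origin_um=(0, -300), z_profile=ZProfile.staircase(32, 80.0))
    brain = ScanRegion(64, 128, 1.0, origin_um=(0, 300))
    pat = scan.build_random_access([eye, brain], transition_lines=2)
    z = scan.apply_z_profile(pat.regions[0])
    assert set(np.round(z, 9)) == {0.0, 80.0}


# ---------------------------------------------------------------------------
# z profiles


def test_halfpipe_profile_shape():
    region = ScanRegion(101, 64, 1.0, z_profile=ZProfile.halfpipe(100.0))
    z = scan.apply_z_profile(region)
    assert z[0] == pytest.approx(0.0, abs=1e-6)
    assert z[-1] == pytest.approx(0.0, abs=1e-6)
    assert np.argmax(z) == 50
    assert z.max() == pytest.approx(100.0)
    # sqrt(cos) argument scaling: quarter point at sqrt(cos(pi/4))
    assert z[25] == pytest.approx(100.0 * math.sqrt(math.cos(math.pi * 0.25)), rel=1e-6)


def test_staircase_two_levels():
    region = ScanRegion(128, 64, 1.0, z_profile=ZProfile.staircase(64, 40.0))
    z = scan.apply_z_profile(region)
    assert set(np.round(z, 9)) == {0.0, 40.0}
    assert (z[:64] == 0).all() and (z[64:] == 40.0).all()


def test_tilted_45_degrees_travel_matches_extent():
    region = ScanRegion(100, 64, 1.0, extent_um=(300.0, 300.0), z_profile=ZProfile.tilted(45.0))
    z = scan.apply_z_profile(region)
    assert z[-1] - z[0] == pytest.approx(300.0, rel=1e-9)  # tan 45 = 1


def test_profile_exceeding_etl_range_names_overshoot():
    cal = scan.EtlCalibration(um_per_dpt=-40.0, max_displacement_um=500.0)
    region = ScanRegion(64, 64, 1.0, z_profile=ZProfile.halfpipe(800.0))
    with pytest.raises(ValueError, match="um"):
        scan.apply_z_profile(region, etl_calibration=cal)


# ---------------------------------------------------------------------------
# waveforms


@pytest.fixture()
def halfpipe_waveforms():
    pat = scan.build_raster(65, 64, 1.0, z_profile=ZProfile.halfpipe(100.0))
    return pat, scan.emit_waveforms(pat, sample_rate_hz=50_000.0, turnaround_fraction=0.1)


def test_waveform_sample_bookkeeping(halfpipe_waveforms):
    pat, wf = halfpipe_waveforms
    assert wf.x_galvo.size == pat.total_lines * wf.samples_per_line
    assert wf.samples_per_line == round(50_000.0 * 1.0e-3)
    report = scan.timing_report(pat)
    assert wf.x_galvo.size / wf.sample_rate_hz * 1e3 == pytest.approx(report.cycle_duration_ms)


def test_pockels_blanking_contract(halfpipe_waveforms):
    _, wf = halfpipe_waveforms
    # every illuminated sample is an active-pixel sample, and vice versa
    assert (wf.pockels[~wf.active_mask] == 0).all()
    assert (wf.pockels[wf.active_mask] > 0).all()


def test_etl_constant_within_lines(halfpipe_waveforms):
    _, wf = halfpipe_waveforms
    per_line = wf.etl_um.reshape(-1, wf.samples_per_line)
    assert (per_line == per_line[:, :1]).all()


def test_halfpipe_etl_peaks_at_centre_line(halfpipe_waveforms):
    _, wf = halfpipe_waveforms
    centre_line = 32
    assert np.argmax(wf.etl_um) // wf.samples_per_line == centre_line


def test_transition_lines_blanked():
    regions = [ScanRegion(16, 16, 1.0), ScanRegion(16, 16, 1.0, origin_um=(100, 0))]
    pat = scan.build_random_access(regions, transition_lines=2)
    wf = scan.emit_waveforms(pat, 10_000.0)
    spl = wf.samples_per_line
    for start in (16 * spl, 17 * spl, (16 + 2 + 16) * spl, (16 + 2 + 17) * spl):
        assert (wf.pockels[start : start + spl] == 0).all()


def test_sample_rate_too_low_rejected():
    with pytest.raises(ValueError, match="sample rate"):
        scan.emit_waveforms(scan.build_raster(8, 8, 1.0), sample_rate_hz=500.0)


# ---------------------------------------------------------------------------
# ETL transient


def _ode_settle(step_um, etl, threshold_um):
    """Independent oracle: integrate the second-order ODE numerically."""
    wn = 2 * math.pi * etl.natural_frequency_hz / 1000.0
    z = etl.damping_ratio

    def rhs(t, y):
        return [y[1], wn * wn * (step_um - y[0]) - 2 * z * wn * y[1]]

    t_end = 25.0 / (z * wn)
    sol = solve_ivp(rhs, (0, t_end), [0.0, 0.0], max_step=0.002, rtol=1e-8, atol=1e-10)
    err = np.abs(sol.y[0] - step_um)
    above = err >= threshold_um
    return float(sol.t[np.nonzero(above)[0][-1]]) if above.any() else 0.0


def test_transient_zero_step():
    settle, _ = scan.etl_transient(0.0)
    assert settle == 0.0


def test_150um_step_settles_within_3ms():
    settle, (t, x) = scan.etl_transient(150.0, threshold_um=5.0)
    assert settle <= 3.0
    assert abs(x[-1] - 150.0) < 1e-9 * 150.0  # converges to the command


def test_transient_matches_ode_oracle():
    etl = EtlModel()
    for step in (40.0, 150.0, 400.0):
        closed, _ = scan.etl_transient(step, etl, threshold_um=5.0)
        oracle = _ode_settle(step, etl, 5.0)
        assert closed == pytest.approx(oracle, abs=0.05)


def test_settle_time_nondecreasing_in_step():
    settles = [scan.etl_transient(s, threshold_um=5.0)[0] for s in (10, 50, 150, 300, 600)]
    assert all(b >= a for a, b in zip(settles, settles[1:]))


def test_transient_converges_for_damping_range():
    for zeta in (0.2, 0.5, 0.8, 1.0):
        etl = EtlModel(damping_ratio=zeta)
        _, (t, x) = scan.etl_transient(150.0, etl, threshold_um=1.0)
        assert abs(x[-1] - 150.0) < 1e-9 * 150.0


# ---------------------------------------------------------------------------
# power compensation


def test_power_compensation_flat_identity():
    pat = scan.build_raster(32, 32, 1.0)
    scales = scan.depth_power_compensation(pat, lambda z: 1.0)
    assert (scales == 1.0).all()


def test_power_compensation_staircase_two_levels():
    pat = scan.build_raster(64, 64, 1.0, z_profile=ZProfile.staircase(32, 100.0))
    scales = scan.depth_power_compensation(pat, lambda z: math.exp(-z / 500.0))
    assert len(set(np.round(scales, 12))) == 2


def test_power_compensation_halfpipe_minimum_at_shallow_lines():
    pat = scan.build_raster(65, 64, 1.0, z_profile=ZProfile.halfpipe(100.0))
    # law increases transmission with depth -> shallowest (edge) lines minimal
    scales = scan.depth_power_compensation(pat, lambda z: 0.5 + 0.004 * z)
    assert np.argmin(scales) in (0, 64)


def test_power_law_out_of_range_rejected():
    pat = scan.build_raster(8, 8, 1.0)
    with pytest.raises(ValueError, match="must be in"):
        scan.depth_power_compensation(pat, lambda z: 1.5)
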