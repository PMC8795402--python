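"""Unit and property tests for the paraxial optics engine."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntcsim import optics
from ntcsim.optics import (
    BeamState,
    free_space,
    thin_lens,
    make_config,
    transfer_matrix,
)

FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# oracles


def ray_fan(config, n_rays=101, etl_power_dpt=0.0):
    """Phase-space ray fan sampling the input Gaussian's caustic ellipse."""
    beam = config.input_beam
    w0 = beam.waist_radius_mm
    theta0 = beam.wavelength_mm / (math.pi * w0)
    phi = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    return np.stack([w0 * np.cos(phi), theta0 * np.sin(phi)])


def ray_fan_focus(config, etl_power_dpt=0.0, n_rays=101):
    """Brute-force best focus: plane of minimal RMS spot after the objective."""
    M = thin_lens(config.objective.effective_focal_length_mm) @ transfer_matrix(
        config, 0.0, config.objective.back_aperture_position_mm, etl_power_dpt
    )
    rays = M @ ray_fan(config, n_rays, etl_power_dpt)
    y, u = rays
    # minimise sum (y + u z)^2 over z -> closed form of the brute-force scan
    z = -float(np.sum(y * u) / np.sum(u * u))
    return z


# ---------------------------------------------------------------------------
# ray matrices


def test_elementary_matrices():
    np.testing.assert_allclose(thin_lens(200.0), [[1, 0], [-1 / 200, 1]])
    np.testing.assert_allclose(free_space(250.0), [[1, 250], [0, 1]])
    with pytest.raises(ValueError):
        thin_lens(0.0)


def test_transfer_matrix_unit_determinant(any_config):
    segments = [(0.0, 200.0), (0.0, optics.OBJECTIVE_POS), (100.0, 350.0)]
    for a, b in segments:
        M = transfer_matrix(any_config, a, b)
        assert abs(np.linalg.det(M) - 1.0) < 1e-12


def test_transfer_matrix_rejects_bad_ranges(dl_config):
    with pytest.raises(ValueError):
        transfer_matrix(dl_config, 100.0, 50.0)
    with pytest.raises(ValueError):
        transfer_matrix(dl_config, 0.0, 1e4)


def test_lagrange_invariant_conserved(any_config):
    """n (y1 u2 - y2 u1) of a chief/marginal pair is conserved along the train."""
    chief = np.array([0.0, 1e-3])
    marginal = np.array([any_config.input_beam.waist_radius_mm, 0.0])
    inv0 = chief[0] * marginal[1] - marginal[0] * chief[1]
    for plane in (100.0, 250.0, 306.6, 380.0, optics.OBJECTIVE_POS):
        M = transfer_matrix(any_config, 0.0, plane)
        c, m = M @ chief, M @ marginal
        inv = c[0] * m[1] - m[0] * c[1]
        assert abs(inv - inv0) <= 1e-9 * abs(inv0)


# ---------------------------------------------------------------------------
# Gaussian transport


def test_rayleigh_range_growth(dl_config):
    """A free waist grows by sqrt(2) after one Rayleigh range."""
    beam = BeamState(wavelength_nm=927.0, waist_radius_mm=0.02, waist_position_mm=0.0)
    zr = beam.rayleigh_range_mm
    state = optics.propagate_gaussian(beam, dl_config, zr)
    assert state.radius_mm == pytest.approx(0.02 * math.sqrt(2.0), rel=1e-9)


def test_collimated_beam_focuses_at_f():
    """A collimated beam through a thin lens waists one focal length on."""
    cfg = make_config("DL")
    beam = BeamState(wavelength_nm=927.0, waist_radius_mm=2.0, waist_position_mm=0.0)
    # the stock scan lens (f=50 at 56.6 mm) is the only lens before 300 mm
    q = optics._beam_q_at(cfg, optics.SCAN_LENS_POS + 1.0, beam=beam)
    waist_after_lens = 1.0 - q.real
    assert waist_after_lens == pytest.approx(50.0, abs=0.05)
    state = optics.propagate_gaussian(beam, cfg, optics.SCAN_LENS_POS + 50.0)
    assert state.radius_mm < 0.02  # focused spot, two orders below the input


def test_gaussian_radius_matches_ray_fan_envelope(ntc1_config):
    """1/e^2 radius at the back aperture equals the 101-ray fan envelope."""
    plane = optics.OBJECTIVE_POS
    state = optics.propagate_gaussian(ntc1_config.input_beam, ntc1_config, plane)
    M = transfer_matrix(ntc1_config, 0.0, plane)
    rays = M @ ray_fan(ntc1_config)
    envelope = float(np.max(np.abs(rays[0])))
    assert envelope == pytest.approx(state.radius_mm, rel=5e-3)


def test_nonphysical_beam_rejected():
    with pytest.raises(ValueError):
        BeamState(waist_radius_mm=-1.0)


@pytest.mark.parametrize("preset,distances", [
    ("DL", [None]),
    ("nTC1", np.linspace(5.0, 100.0, 11)),
    ("nTC2", np.linspace(5.0, 100.0, 11)),
])
def test_gaussian_focus_agrees_with_ray_fan(preset, distances):
    """Gaussian focal distance vs brute-force ray-fan focus, <= 0.5%."""
    for d in distances:
        cfg = make_config(preset, None if d is None else float(d))
        v_gauss = optics.focus_solution(cfg).focal_distance_mm
        v_fan = ray_fan_focus(cfg)
        assert abs(v_gauss - v_fan) <= 5e-3 * abs(v_gauss)


# ---------------------------------------------------------------------------
# IFP


def test_ifp_positions_match_thin_lens_oracle():
    # stock train: 50 mm focus after the f=50 scan lens
    ifp = optics.find_ifp(make_config("DL"))
    assert ifp.position_mm == pytest.approx(optics.SCAN_LENS_POS + 50.0, abs=1e-9)
    # nTC1, L2 100 mm from the tube lens: residual convergence 100 mm past
    # L2 meets f=175 -> v = 175*100/275 = 63.64 mm after L2
    ifp = optics.find_ifp(make_config("nTC1", 100.0))
    assert ifp.relative_to_tube_lens_mm == pytest.approx(-(100.0 - 175.0 * 100.0 / 275.0), abs=1e-6)
    # nTC2, L3 100 mm out: 1/v = 1/200 + 1/100 -> 66.7 mm beyond the tube
    # lens, i.e. between tube lens and aperture: divergent at the aperture
    ifp = optics.find_ifp(make_config("nTC2", 100.0))
    assert ifp.relative_to_tube_lens_mm == pytest.approx(200.0 / 3.0, abs=1e-6)
    assert 0.0 < ifp.relative_to_tube_lens_mm < 95.0


def test_ifp_side_of_tube_lens():
    """nTC1 keeps the IFP upstream of the tube lens; nTC2 beyond it."""
    for d in (20.0, 50.0, 100.0):
        assert optics.find_ifp(make_config("nTC1", d)).relative_to_tube_lens_mm < 0
        assert optics.find_ifp(make_config("nTC2", d)).relative_to_tube_lens_mm > 0


# ---------------------------------------------------------------------------
# focus solutions


def test_dl_axis_is_reference(dl_config):
    sol = optics.focus_solution(dl_config)
    # axial reference: on-axis stock focus defines z = 0 (the residual is
    # the negligible Gaussian focal shift of the near-collimated beam)
    assert sol.focus_point_um == pytest.approx((0.0, 0.0, 0.0), abs=1e-3)
    assert sol.effective_na == pytest.approx(0.6755, abs=2e-3)


def test_ntc_focus_beyond_nominal_plane():
    """Diverging aperture beams focus beyond the nominal working distance."""
    for preset, d in [("nTC1", 100.0), ("nTC1", 5.0), ("nTC2", 100.0)]:
        z = optics.focus_solution(make_config(preset, d)).focus_point_um[2]
        assert z > 0


def test_lateral_antisymmetry_axial_evenness(any_config):
    th = 1.5
    a = optics.focus_solution(any_config, th, -0.7)
    b = optics.focus_solution(any_config, -th, 0.7)
    assert a.focus_point_um[0] == pytest.approx(-b.focus_point_um[0], rel=1e-12)
    assert a.focus_point_um[1] == pytest.approx(-b.focus_point_um[1], rel=1e-12)
    assert a.focus_point_um[2] == pytest.approx(b.focus_point_um[2], rel=1e-12)


def test_angle_beyond_mirror_range_rejected(dl_config):
    with pytest.raises(ValueError):
        optics.focus_solution(dl_config, 10.0, 0.0)


# ---------------------------------------------------------------------------
# field of view


def test_dl_fov_square_and_round(dl_config):
    fov = optics.fov_diameter(dl_config)
    assert fov.mirror_limited_square_mm == pytest.approx(0.5, rel=1e-6)
    assert fov.mirror_limited_diameter_mm == pytest.approx(0.5 * math.sqrt(2.0), rel=1e-6)
    assert fov.binding_limit == "mirror"


def test_fov_linear_in_mirror_angle(ntc1_config):
    base = optics.fov_diameter(ntc1_config)
    half = ntc1_config.mirrors.max_optical_half_angle_deg
    doubled = replace(
        ntc1_config, mirrors=replace(ntc1_config.mirrors, max_optical_half_angle_deg=2 * half)
    )
    fov2 = optics.fov_diameter(doubled)
    # paraxial chief trace: strictly linear while mirror-limited
    assert fov2.mirror_limited_square_mm == pytest.approx(
        2.0 * base.mirror_limited_square_mm, rel=1e-9
    )


def test_fov_requires_calibrated_mirror(dl_config):
    cfg = replace(dl_config, mirrors=replace(dl_config.mirrors, max_optical_half_angle_deg=None))
    with pytest.raises(ValueError, match="calibrat"):
        optics.fov_diameter(cfg)


# ---------------------------------------------------------------------------
# field curvature


def test_sagitta_nonnegative_and_quadratic():
    """Edges focus shallower; sagitta follows r^2/2R with R ~ focal distance."""
    cfg = make_config("nTC1", 5.0)
    v = optics.focus_solution(cfg).focal_distance_mm
    rs = np.linspace(0.1, 0.9, 9)
    sags = np.array([optics.field_curvature_sagitta(cfg, 2 * r) for r in rs])
    assert np.all(sags > 0)
    coef = np.polyfit(rs**2, sags, 1)
    fit = np.polyval(coef, rs**2)
    ss_res = np.sum((sags - fit) ** 2)
    ss_tot = np.sum((sags - sags.mean()) ** 2)
    assert 1 - ss_res / ss_tot > 0.99
    r_sphere = 1.0 / (2.0 * coef[0] * 1e-3)  # sag in um
    assert r_sphere == pytest.approx(v, rel=0.02)


def test_dl_field_nearly_flat(dl_config):
    """Telecentric stock field: a few um of residual curvature at most."""
    sag = optics.field_curvature_sagitta(dl_config, 0.5)
    assert 0 <= sag < 5.0


# ---------------------------------------------------------------------------
# N.A. and PSF closed forms


def test_effective_na_ordering_across_configs():
    nas = [optics.effective_na(make_config(p, d)) for p, d in [
        ("DL", None), ("nTC1", 100.0), ("nTC1", 5.0), ("nTC2", 100.0), ("nTC2", 5.0)
    ]]
    assert all(a > b for a, b in zip(nas, nas[1:]))


def test_effective_na_never_exceeds_objective(any_config):
    assert 0 < optics.effective_na(any_config) <= any_config.objective.max_na


def test_na_recovered_from_axial_anchor(dl_config):
    """Inverting the axial closed form at 3.15 um recovers the stock N.A."""
    from scipy.optimize import brentq

    def axial(na):
        return optics.psf_fwhm(na).axial_fwhm_um

    na = brentq(lambda x: axial(x) - 3.15, 0.1, 1.3, xtol=1e-12)
    assert optics.effective_na(dl_config) == pytest.approx(na, rel=1e-3)
    assert optics.predict_psf(dl_config).axial_fwhm_um == pytest.approx(3.15, rel=1e-3)


def test_psf_low_na_scaling():
    a = optics.psf_fwhm(0.10)
    b = optics.psf_fwhm(0.05)
    assert b.lateral_fwhm_um == pytest.approx(2.0 * a.lateral_fwhm_um, rel=1e-6)
    assert b.axial_fwhm_um == pytest.approx(4.0 * a.axial_fwhm_um, rel=5e-3)


def test_psf_axial_exceeds_lateral():
    for na in (0.05, 0.3, 0.7, 1.0, 1.32):
        p = optics.psf_fwhm(na)
        assert p.axial_fwhm_um > p.lateral_fwhm_um > 0


def test_psf_evanescent_rejected():
    with pytest.raises(ValueError):
        optics.psf_fwhm(1.34)


@settings(max_examples=60, deadline=None)
@given(st.floats(min_value=0.02, max_value=1.25), st.floats(min_value=1.001, max_value=1.3))
def test_psf_monotone_decreasing_in_na(na, factor):
    lo, hi = optics.psf_fwhm(na), optics.psf_fwhm(min(na * factor, 1.3))
    assert hi.lateral_fwhm_um < lo.lateral_fwhm_um
    assert hi.axial_fwhm_um < lo.axial_fwhm_um


# ---------------------------------------------------------------------------
# ETL


def test_etl_zero_current_zero_shift(ntc1_config):
    assert optics.etl_current_to_focus_shift(ntc1_config, 0.0) == 0.0


def test_etl_anchor_600um(ntc1_config):
    assert abs(optics.etl_current_to_focus_shift(ntc1_config, 50.0)) == pytest.approx(
        600.0, rel=1e-3
    )


def test_etl_shift_monotone(ntc1_config):
    """|dz| strictly increasing over 0-50 mA (oracle: focus_solution grid)."""
    shifts = [abs(optics.etl_current_to_focus_shift(ntc1_config, c)) for c in np.linspace(0, 50, 11)]
    assert all(b > a for a, b in zip(shifts, shifts[1:]))


def test_etl_overcurrent_rejected(ntc1_config):
    with pytest.raises(ValueError):
        optics.etl_current_to_focus_shift(ntc1_config, 400.0)


# ---------------------------------------------------------------------------
# calibration


def test_calibrate_roundtrip_recovers_parameters():
    """Observables generated from known parameters are refit to <= 1e-6."""
    truth = {"waist_radius_mm": 1.21, "max_half_angle_deg": 4.3, "diopter_per_mA": 0.042}
    cfg = make_config(
        "nTC1", 100.0,
        waist_radius_mm=truth["waist_radius_mm"],
        max_half_angle_deg=truth["max_half_angle_deg"],
        diopter_per_mA=truth["diopter_per_mA"],
    )
    observables = [
        ("dl_psf_axial_um", optics._predict_observable(cfg, "dl_psf_axial_um")),
        ("dl_square_fov_mm", optics._predict_observable(cfg, "dl_square_fov_mm")),
        ("etl_shift_um_at_50mA", optics._predict_observable(cfg, "etl_shift_um_at_50mA")),
    ]
    fresh = make_config("nTC1", 100.0)
    result = optics.calibrate(fresh, observables)
    for name, val in truth.items():
        assert result.fitted[name] == pytest.approx(val, rel=1e-6)


def test_calibrate_square_fov_anchor():
    result = optics.calibrate(make_config("DL"), [("dl_square_fov_mm", 0.5)])
    cfg = result.config
    assert optics.fov_diameter(cfg).mirror_limited_square_mm == pytest.approx(0.5, rel=1e-9)


def test_calibrate_contradictory_duplicates_surface_residual():
    result = optics.calibrate(
        make_config("DL"), [("dl_square_fov_mm", 0.5), ("dl_square_fov_mm", 5.0)]
    )
    assert len(result.residuals) == 2
    assert any(abs(r) > 0.1 for r in result.residuals.values())


def test_calibrate_errors():
    with pytest.raises(ValueError):
        optics.calibrate(make_config("DL"), [])
    with pytest.raises(ValueError, match="insufficient"):
        optics.calibrate(
            make_config("DL"), [("dl_square_fov_mm", 0.5)], fit_params=["waist_radius_mm"]
        )
    with pytest.raises(ValueError, match="unknown observable"):
        optics.calibrate(make_config("DL"), [("bogus", 1.0)])


def test_objective_aperture_sanity_warning():
    with pytest.warns(UserWarning, match="back aperture"):
        optics.ObjectiveModel(back_aperture_diameter_mm=10.0)
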