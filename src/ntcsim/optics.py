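"""Paraxial model of a non-telecentric (nTC) two-photon excitation path.

The excitation path of a galvo–galvo two-photon microscope is modelled as a
train of ideal thin lenses along an unfolded optical axis.  The path
coordinate increases from the scan-mirror pivot (0 mm) toward the sample.
Three presets are provided:

``DL``
    The stock diffraction-limited path: scan lens (f = 50 mm, 56.6 mm from
    the mirrors) and tube lens (f = 200 mm) separated by the sum of their
    focal lengths (250 mm), so a collimated beam pivots about the objective
    back aperture.

``nTC1``
    The scan lens is replaced by a 190 mm lens (L1) fixed 190 mm in front of
    the tube lens — placing an intermediary focal point (IFP) exactly at the
    tube lens — plus a 175 mm lens (L2) whose distance from the tube lens
    (5–100 mm) tunes the IFP and with it the divergence at the back
    aperture.

``nTC2``
    The scan lens is replaced by a single 200 mm lens (L3) 5–100 mm in front
    of the tube lens; the convergence point now lies beyond the tube lens.

A diverging beam at the back aperture lowers the effective excitation N.A.,
elongates the two-photon point spread function, pushes the focus beyond the
nominal working distance, and multiplies the lateral scan magnification —
the field-of-view expansion that motivates the design.

Beam transport uses 2x2 ray (ABCD) matrices for chief/marginal rays and the
complex beam parameter for Gaussian beams.  The objective is an ideal thin
lens of effective focal length 8.25 mm (a x20 objective on a 165 mm
reference tube length) placed 95 mm beyond the tube lens, with a back
aperture of 16.5 mm diameter.  Axial sample coordinates are air-equivalent
millimetres relative to the nominal focal plane; the immersion index enters
only through the N.A. and PSF closed forms.

Free parameters that the underlying hardware does not print — the input
beam 1/e^2 radius at the mirrors, the usable optical scan half-angle, and
the tunable-lens diopter-per-milliamp gain — are anchored to measurable
quantities by :func:`calibrate`; module defaults store the result of that
calibration against the stock configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "OpticalElement",
    "ObjectiveModel",
    "BeamState",
    "ScanMirrorModel",
    "EtlModel",
    "OpticalConfig",
    "FocusSolution",
    "PsfPrediction",
    "FovReport",
    "IfpResult",
    "CalibrationResult",
    "make_config",
    "thin_lens",
    "free_space",
    "transfer_matrix",
    "propagate_gaussian",
    "find_ifp",
    "focus_solution",
    "effective_na",
    "psf_fwhm",
    "fov_diameter",
    "field_curvature_sagitta",
    "etl_current_to_focus_shift",
    "calibrate",
    "gaussian_aperture_transmission",
]

# ---------------------------------------------------------------------------
# Geometry constants (mm along the unfolded path, measured from the mirror
# pivot).  The movable head places the objective back aperture 95 mm beyond
# the tube lens at its centre position.
SCAN_LENS_POS = 56.6
SCAN_LENS_F = 50.0
TUBE_LENS_POS = SCAN_LENS_POS + 250.0  # 306.6
TUBE_LENS_F = 200.0
OBJECTIVE_POS = TUBE_LENS_POS + 95.0  # 401.6

L1_F = 190.0
L2_F = 175.0
L3_F = 200.0

DEFAULT_WAVELENGTH_NM = 927.0
IMMERSION_INDEX = 1.33

# Default calibration, derived once from three anchors (see `calibrate`):
#   * input waist from the stock-path axial two-photon PSF FWHM of 3.15 um,
#   * optical scan half-angle from the stock 0.5 mm square field,
#   * ETL gain from the 600 um plane shift at 50 mA in nTC1.
DEFAULT_WAIST_RADIUS_MM = 1.393298
DEFAULT_MAX_HALF_ANGLE_DEG = 6.944943
DEFAULT_DIOPTER_PER_MA = 0.06169707

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class OpticalElement:
    """A thin lens or an explicit free-space gap on the unfolded path."""

    kind: str  # "thin-lens" | "free-space"
    axial_position_mm: float
    focal_length_mm: float | None = None
    length_mm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("thin-lens", "free-space"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "thin-lens":
            if not self.focal_length_mm:
                raise ValueError("thin lens requires a nonzero focal length")
        elif self.length_mm is None or self.length_mm < 0:
            raise ValueError("free-space element requires length_mm >= 0")


@dataclass(frozen=True)
class ObjectiveModel:
    """Ideal-thin-lens stand-in for the high-N.A. water-immersion objective."""

    effective_focal_length_mm: float = 8.25
    max_na: float = 1.0
    back_aperture_diameter_mm: float = 16.5
    nominal_working_distance_mm: float = 1.8
    immersion_index: float = IMMERSION_INDEX
    back_aperture_position_mm: float = OBJECTIVE_POS

    def __post_init__(self) -> None:
        if self.immersion_index < 1:
            raise ValueError("immersion_index must be >= 1")
        if self.nominal_working_distance_mm <= 0:
            raise ValueError("nominal_working_distance_mm must be > 0")
        expected = 2.0 * self.max_na * self.effective_focal_length_mm
        if abs(self.back_aperture_diameter_mm - expected) > 0.1 * expected:
            warnings.warn(
                "back aperture diameter deviates >10% from 2*NA*EFL "
                f"({self.back_aperture_diameter_mm:.2f} vs {expected:.2f} mm)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BeamState:
    """Gaussian beam described by its waist (1/e^2 intensity radius)."""

    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    waist_radius_mm: float = DEFAULT_WAIST_RADIUS_MM
    waist_position_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.waist_radius_mm <= 0:
            raise ValueError("waist_radius_mm must be > 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")

    @property
    def wavelength_mm(self) -> float:
        return self.wavelength_nm * 1e-6

    @property
    def rayleigh_range_mm(self) -> float:
        return math.pi * self.waist_radius_mm**2 / self.wavelength_mm

    def q_at_waist(self) -> complex:
        return 1j * self.rayleigh_range_mm


@dataclass(frozen=True)
class ScanMirrorModel:
    """Both galvos collapsed onto a single pivot at the path origin."""

    pivot_position_mm: float = 0.0
    max_optical_half_angle_deg: float | None = DEFAULT_MAX_HALF_ANGLE_DEG
    distance_to_first_element_mm: float = SCAN_LENS_POS

    def __post_init__(self) -> None:
        if (
            self.max_optical_half_angle_deg is not None
            and self.max_optical_half_angle_deg <= 0
        ):
            raise ValueError("max_optical_half_angle_deg must be > 0")


@dataclass(frozen=True)
class EtlModel:
    """Electrically tunable lens 200 mm upstream of the mirror pivot."""

    position_mm: float = -200.0
    diopter_per_mA: float = DEFAULT_DIOPTER_PER_MA
    max_current_mA: float = 300.0
    natural_frequency_hz: float = 450.0
    damping_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.max_current_mA <= 0:
            raise ValueError("max_current_mA must be > 0")
        if not (0 < self.damping_ratio <= 1):
            raise ValueError("damping_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class OpticalConfig:
    """A named lens train plus objective, mirror, ETL and input-beam models."""

    preset: str
    elements: tuple[OpticalElement, ...]
    objective: ObjectiveModel = ObjectiveModel()
    mirrors: ScanMirrorModel = ScanMirrorModel()
    etl: EtlModel = EtlModel()
    input_beam: BeamState = BeamState()
    movable_lens_distance_mm: float | None = None

    def __post_init__(self) -> None:
        positions = [e.axial_position_mm for e in self.elements]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("element positions must strictly increase")

    @property
    def lenses(self) -> tuple[OpticalElement, ...]:
        """All thin lenses including the objective, ordered along the path."""
        obj = OpticalElement(
            "thin-lens",
            self.objective.back_aperture_position_mm,
            self.objective.effective_focal_length_mm,
            label="objective",
        )
        return tuple(e for e in self.elements if e.kind == "thin-lens") + (obj,)


@dataclass(frozen=True)
class PsfPrediction:
    lateral_fwhm_um: float
    axial_fwhm_um: float

    def __post_init__(self) -> None:
        if not (self.axial_fwhm_um >= self.lateral_fwhm_um > 0):
            raise ValueError("require axial_fwhm >= lateral_fwhm > 0")


@dataclass(frozen=True)
class IfpResult:
    """Last real beam waist (intermediary focal point) upstream of the objective."""

    position_mm: float | None  # along the path; None when the output is collimated
    relative_to_tube_lens_mm: float | None  # >0 means beyond the tube lens
    collimated: bool = False
    label: str = ""


@dataclass(frozen=True)
class FocusSolution:
    focus_point_um: tuple[float, float, float]
    effective_na: float
    beam_radius_at_aperture_mm: float
    divergence_half_angle_at_aperture_rad: float
    ifp: IfpResult
    vignetting_fraction: float
    fully_vignetted: bool = False
    focal_distance_mm: float = 0.0  # Gaussian focus distance below the objective


@dataclass(frozen=True)
class FovReport:
    mirror_limited_square_mm: float
    mirror_limited_diameter_mm: float
    vignette_limited_diameter_mm: float
    usable_diameter_mm: float
    binding_limit: str  # "mirror" | "vignetting"
    clip_threshold: float


@dataclass(frozen=True)
class CalibrationResult:
    fitted: dict[str, float]
    residuals: dict[str, float]
    config: "OpticalConfig"
    cost: float


# ---------------------------------------------------------------------------
# Construction


def _train_elements(preset: str, lens_distance_mm: float | None) -> tuple[OpticalElement, ...]:
    d = lens_distance_mm
    if preset == "DL":
        return (
            OpticalElement("thin-lens", SCAN_LENS_POS, SCAN_LENS_F, label="scan lens"),
            OpticalElement("thin-lens", TUBE_LENS_POS, TUBE_LENS_F, label="tube lens"),
        )
    if d is None:
        d = 5.0
    if not (0.0 < d <= 100.0):
        raise ValueError("movable lens distance must lie in (0, 100] mm from the tube lens")
    if preset == "nTC1":
        if d >= 190.0 - 1e-9:
            raise ValueError("L2 must sit between L1 and the tube lens")
        return (
            OpticalElement("thin-lens", TUBE_LENS_POS - 190.0, L1_F, label="L1"),
            OpticalElement("thin-lens", TUBE_LENS_POS - d, L2_F, label="L2"),
            OpticalElement("thin-lens", TUBE_LENS_POS, TUBE_LENS_F, label="tube lens"),
        )
    if preset == "nTC2":
        return (
            OpticalElement("thin-lens", TUBE_LENS_POS - d, L3_F, label="L3"),
            OpticalElement("thin-lens", TUBE_LENS_POS, TUBE_LENS_F, label="tube lens"),
        )
    raise ValueError(f"unknown preset {preset!r}; expected DL, nTC1 or nTC2")


def make_config(
    preset: str,
    lens_distance_mm: float | None = None,
    *,
    waist_radius_mm: float = DEFAULT_WAIST_RADIUS_MM,
    max_half_angle_deg: float | None = DEFAULT_MAX_HALF_ANGLE_DEG,
    diopter_per_mA: float = DEFAULT_DIOPTER_PER_MA,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
) -> OpticalConfig:
    """Build one of the three presets.

    ``lens_distance_mm`` is the distance of the movable lens (L2 for nTC1,
    L3 for nTC2) from the tube lens; it is ignored for the DL preset.
    """
    elements = _train_elements(preset, lens_distance_mm)
    return OpticalConfig(
        preset=preset,
        elements=elements,
        mirrors=ScanMirrorModel(max_optical_half_angle_deg=max_half_angle_deg),
        etl=EtlModel(diopter_per_mA=diopter_per_mA),
        input_beam=BeamState(wavelength_nm=wavelength_nm, waist_radius_mm=waist_radius_mm),
        movable_lens_distance_mm=None if preset == "DL" else (lens_distance_mm or 5.0),
    )


# ---------------------------------------------------------------------------
# Ray matrices


def thin_lens(focal_length_mm: float) -> np.ndarray:
    if focal_length_mm == 0:
        raise ValueError("zero focal length")
    return np.array([[1.0, 0.0], [-1.0 / focal_length_mm, 1.0]])


def free_space(distance_mm: float) -> np.ndarray:
    return np.array([[1.0, distance_mm], [0.0, 1.0]])


def _etl_lens(config: OpticalConfig, etl_power_dpt: float) -> list[OpticalElement]:
    if etl_power_dpt == 0.0:
        return []
    f_mm = 1000.0 / etl_power_dpt
    return [OpticalElement("thin-lens", config.etl.position_mm, f_mm, label="ETL")]


def transfer_matrix(
    config: OpticalConfig,
    from_position_mm: float,
    to_position_mm: float,
    etl_power_dpt: float = 0.0,
) -> np.ndarray:
    """Composed ABCD matrix between two planes on the path.

    Thin lenses strictly inside ``(from_position_mm, to_position_mm)`` are
    applied: a plane at a lens coordinate sits just *before* that lens, so
    the mirror-to-back-aperture matrix excludes the objective refraction.
    Determinant is 1 because entry and exit media share the same
    (air-equivalent) index.
    """
    if from_position_mm >= to_position_mm:
        raise ValueError("from_position must be < to_position")
    lo = config.etl.position_mm
    hi = config.objective.back_aperture_position_mm
    if from_position_mm < lo - 1e-9 or to_position_mm > hi + 1e-9:
        raise ValueError(
            f"positions must lie within the modelled path [{lo}, {hi}] mm"
        )
    lenses = sorted(
        list(config.lenses) + _etl_lens(config, etl_power_dpt),
        key=lambda e: e.axial_position_mm,
    )
    M = np.eye(2)
    s = from_position_mm
    for lens in lenses:
        p = lens.axial_position_mm
        if p <= from_position_mm or p >= to_position_mm:
            continue
        M = thin_lens(lens.focal_length_mm) @ free_space(p - s) @ M
        s = p
    return free_space(to_position_mm - s) @ M


# ---------------------------------------------------------------------------
# Gaussian transport


@dataclass(frozen=True)
class GaussianState:
    """Beam parameters at one plane: 1/e^2 radius and wavefront curvature."""

    position_mm: float
    radius_mm: float
    wavefront_radius_mm: float  # inf for a flat wavefront
    q: complex
    wavelength_nm: float


def _q_transform(q: complex, M: np.ndarray) -> complex:
    a, b, c, d = M.ravel()
    return (a * q + b) / (c * q + d)


def _beam_q_at(
    config: OpticalConfig,
    to_position_mm: float,
    etl_power_dpt: float = 0.0,
    beam: BeamState | None = None,
) -> complex:
    """Complex beam parameter at a plane (just before any lens there).

    The tunable lens sits upstream of the mirror pivot; its refraction is
    applied by carrying the beam parameter to the ETL plane, refracting,
    and returning — algebraically exact for an ideal Gaussian beam.
    """
    beam = beam or config.input_beam
    q = beam.q_at_waist()
    s = beam.waist_position_mm
    if etl_power_dpt:
        q = q + (config.etl.position_mm - s)
        q = _q_transform(q, thin_lens(1000.0 / etl_power_dpt))
        q = q + (s - config.etl.position_mm)
    return _q_transform(q, transfer_matrix(config, s, to_position_mm))


def propagate_gaussian(
    beam: BeamState,
    config: OpticalConfig,
    to_position_mm: float,
    etl_power_dpt: float = 0.0,
) -> GaussianState:
    """Transport a Gaussian beam to a plane via the complex beam parameter."""
    q = _beam_q_at(config, to_position_mm, etl_power_dpt, beam)
    lam = beam.wavelength_mm
    inv_q = 1.0 / q
    radius = math.sqrt(-lam / (math.pi * inv_q.imag))
    curvature = math.inf if abs(inv_q.real) < 1e-15 else 1.0 / inv_q.real
    return GaussianState(to_position_mm, radius, curvature, q, beam.wavelength_nm)


def _q_after_objective(config: OpticalConfig, etl_power_dpt: float = 0.0) -> complex:
    q = _beam_q_at(config, config.objective.back_aperture_position_mm, etl_power_dpt)
    # objective refraction at the aperture plane
    return _q_transform(q, thin_lens(config.objective.effective_focal_length_mm))


def _focal_distance_mm(config: OpticalConfig, etl_power_dpt: float = 0.0) -> tuple[float, float]:
    """(distance of the Gaussian waist below the objective, Rayleigh range)."""
    q = _q_after_objective(config, etl_power_dpt)
    return -q.real, q.imag


def find_ifp(config: OpticalConfig, etl_power_dpt: float = 0.0) -> IfpResult:
    """Locate the intermediary focal point before the objective.

    Traces a marginal ray (launched parallel at the input-beam radius) and
    returns the last axis crossing upstream of the back aperture.  With no
    crossing, a parallel exit ray reports ``collimated`` (the stock train)
    and a still-converging exit ray reports the virtual crossing beyond the
    aperture.
    """
    beam = config.input_beam
    lenses = sorted(
        [e for e in config.elements if e.kind == "thin-lens"]
        + _etl_lens(config, etl_power_dpt),
        key=lambda e: e.axial_position_mm,
    )
    obj_pos = config.objective.back_aperture_position_mm
    y, u = beam.waist_radius_mm, 0.0
    s = beam.waist_position_mm
    crossings: list[float] = []
    boundaries = [e.axial_position_mm for e in lenses] + [obj_pos]
    for lens, nxt in zip(lenses, boundaries[1:]):
        p = lens.axial_position_mm
        y, u = y + u * (p - s), u
        u = u - y / lens.focal_length_mm
        s = p
        if u != 0.0:
            cross = s - y / u
            if s < cross <= nxt:
                crossings.append(cross)
    if crossings:
        pos = crossings[-1]
        return IfpResult(pos, pos - TUBE_LENS_POS)
    if abs(u) < 1e-12:
        return IfpResult(None, None, collimated=True, label="collimated")
    pos = s - y / u  # beyond the back aperture: virtual for the objective
    return IfpResult(pos, pos - TUBE_LENS_POS, label="virtual (beyond back aperture)")


def gaussian_aperture_transmission(
    beam_radius_mm: float, offset_mm: float, aperture_radius_mm: float
) -> float:
    """Power fraction of an offset Gaussian beam passing a circular aperture.

    Deterministic polar quadrature; accurate to ~1e-4 which is ample for a
    50%-transmission clip criterion.
    """
    if beam_radius_mm <= 0:
        raise ValueError("beam_radius_mm must be > 0")
    r = np.linspace(0.0, aperture_radius_mm, 240)
    phi = np.linspace(0.0, math.pi, 120)  # symmetric in phi
    rr, pp = np.meshgrid(r, phi, indexing="ij")
    d2 = rr**2 + offset_mm**2 - 2.0 * rr * offset_mm * np.cos(pp)
    w2 = beam_radius_mm**2
    integ = np.exp(-2.0 * d2 / w2) * rr
    total = np.trapezoid(np.trapezoid(integ, phi, axis=1), r)
    return float(2.0 * total * 2.0 / (math.pi * w2))  # x2 for the half-plane


def focus_solution(
    config: OpticalConfig,
    theta_x_deg: float = 0.0,
    theta_y_deg: float = 0.0,
    etl_power_dpt: float = 0.0,
) -> FocusSolution:
    """Where the beam focuses for a given mirror/ETL state.

    The chief ray (launched from the mirror pivot at the optical scan angle)
    fixes the lateral focus position; the complex-beam-parameter transport
    fixes the focal distance, effective N.A. and aperture-plane beam size.
    The focal surface is modelled as a sphere centred on the back aperture
    with radius equal to the on-axis focal distance, which reproduces the
    measured shallower-at-the-edges field curvature of large-field scans.
    """
    mirrors = config.mirrors
    if mirrors.max_optical_half_angle_deg is not None:
        lim = mirrors.max_optical_half_angle_deg + 1e-9
        if abs(theta_x_deg) > lim or abs(theta_y_deg) > lim:
            raise ValueError("scan angle exceeds the calibrated mirror half-angle")
    current = etl_power_dpt / config.etl.diopter_per_mA if config.etl.diopter_per_mA else 0.0
    if abs(current) > config.etl.max_current_mA + 1e-9:
        raise ValueError("implied ETL current exceeds max_current")

    obj = config.objective
    ap_pos = obj.back_aperture_position_mm
    f_obj = obj.effective_focal_length_mm

    v, z_r = _focal_distance_mm(config, etl_power_dpt)
    w_waist = math.sqrt(z_r * config.input_beam.wavelength_mm / math.pi)

    # chief ray through the train (per transverse axis; the train is
    # rotationally symmetric so one matrix serves both)
    M_ap = transfer_matrix(config, 0.0, ap_pos, etl_power_dpt)
    M_full = thin_lens(f_obj) @ M_ap
    tx = math.radians(theta_x_deg)
    ty = math.radians(theta_y_deg)
    yx_ap, _ = M_ap @ (0.0, tx)
    yy_ap, _ = M_ap @ (0.0, ty)
    cx, cux = M_full @ (0.0, tx)
    cy, cuy = M_full @ (0.0, ty)
    x_mm = cx + cux * v
    y_mm = cy + cuy * v

    # beam footprint and divergence at the aperture plane
    q_ap = _beam_q_at(config, ap_pos, etl_power_dpt)
    lam = config.input_beam.wavelength_mm
    inv_q = 1.0 / q_ap
    w_ap = math.sqrt(-lam / (math.pi * inv_q.imag))
    curvature = inv_q.real  # 1/R; > 0 diverging
    div_half_angle = abs(curvature) * w_ap  # marginal slope at the aperture

    # vignetting: offset Gaussian against the circular back aperture
    offset = math.hypot(yx_ap, yy_ap)
    transmission = gaussian_aperture_transmission(w_ap, offset, obj.back_aperture_diameter_mm / 2.0)
    vignetting = min(max(1.0 - transmission, 0.0), 1.0)
    fully = transmission < 1e-3

    # effective N.A. from the focused Gaussian far field, clipped at the
    # aperture-limited cone
    na_gauss = lam / (math.pi * w_waist)
    na_aperture = obj.back_aperture_diameter_mm / 2.0 / v if v > 0 else obj.max_na
    na = min(na_gauss, abs(na_aperture), obj.max_na)

    # spherical focal cap: constant focal distance from the aperture centre
    r_mm = math.hypot(x_mm, y_mm)
    if v > 0 and r_mm < v:
        z_mm = math.sqrt(v * v - r_mm * r_mm) - f_obj
    else:
        z_mm = v - f_obj  # degenerate (virtual focus or off the cap)
    return FocusSolution(
        focus_point_um=(x_mm * 1e3, y_mm * 1e3, z_mm * 1e3),
        effective_na=na,
        beam_radius_at_aperture_mm=w_ap,
        divergence_half_angle_at_aperture_rad=div_half_angle,
        ifp=find_ifp(config, etl_power_dpt),
        vignetting_fraction=vignetting,
        fully_vignetted=fully,
        focal_distance_mm=v,
    )


def effective_na(config: OpticalConfig, etl_power_dpt: float = 0.0) -> float:
    """Effective excitation N.A. of the focused cone in the immersion medium."""
    return focus_solution(config, 0.0, 0.0, etl_power_dpt).effective_na


# ---------------------------------------------------------------------------
# PSF closed forms


def psf_fwhm(
    effective_na: float,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    immersion_index: float = IMMERSION_INDEX,
) -> PsfPrediction:
    """Two-photon (squared-intensity) Gaussian-focus FWHMs.

    Standard Gaussian-focus illumination closed forms with the squared
    intensity of two-photon excitation; the lateral form switches between a
    low- and a high-N.A. branch at N.A. 0.7.  FWHM = 2*sqrt(ln 2) times the
    1/e radius of the two-photon excitation profile.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    if effective_na <= 0:
        raise ValueError("effective_na must be > 0")
    if effective_na >= immersion_index:
        raise ValueError("effective_na >= immersion index (evanescent regime)")
    lam_um = wavelength_nm * 1e-3
    n = immersion_index
    root2 = math.sqrt(2.0)
    if effective_na <= 0.7:
        w_xy = 0.320 * lam_um / (root2 * effective_na)
    else:
        w_xy = 0.325 * lam_um / (root2 * effective_na**0.91)
    w_z = (0.532 * lam_um / root2) * (1.0 / (n - math.sqrt(n * n - effective_na**2)))
    k = 2.0 * math.sqrt(math.log(2.0))
    return PsfPrediction(lateral_fwhm_um=k * w_xy, axial_fwhm_um=k * w_z)


def predict_psf(config: OpticalConfig, etl_power_dpt: float = 0.0) -> PsfPrediction:
    """Convenience: closed-form PSF for a configuration's effective N.A."""
    return psf_fwhm(
        effective_na(config, etl_power_dpt),
        config.input_beam.wavelength_nm,
        config.objective.immersion_index,
    )


# ---------------------------------------------------------------------------
# Field of view and curvature


def _lateral_mm_per_rad(config: OpticalConfig) -> float:
    sol = focus_solution(config, 1e-3, 0.0)  # 1 mdeg is well inside any range
    return abs(sol.focus_point_um[0]) * 1e-3 / math.radians(1e-3)


def fov_diameter(config: OpticalConfig, clip_threshold: float = 0.5) -> FovReport:
    """Usable field diameter: min of mirror-range and vignetting limits.

    The mirror-limited square side is twice the lateral focus shift at the
    calibrated half-angle; its circumscribed circle is the round
    mirror-limited diameter.  The vignetting limit is where aperture
    transmission of the walking beam drops below ``clip_threshold``.
    """
    half = config.mirrors.max_optical_half_angle_deg
    if half is None:
        raise ValueError(
            "mirror range not calibrated: set max_optical_half_angle_deg "
            "(e.g. via calibrate with a field-of-view observable)"
        )
    scale = _lateral_mm_per_rad(config)
    square = 2.0 * scale * math.radians(half)
    round_d = square * math.sqrt(2.0)

    sol0 = focus_solution(config)
    ap_r = config.objective.back_aperture_diameter_mm / 2.0
    M_ap = transfer_matrix(config, 0.0, config.objective.back_aperture_position_mm)
    walk_per_rad = abs((M_ap @ (0.0, 1.0))[0])
    w_ap = sol0.beam_radius_at_aperture_mm

    def trans(theta_rad: float) -> float:
        return gaussian_aperture_transmission(w_ap, walk_per_rad * theta_rad, ap_r)

    # bracket the clip angle; beyond ~1.5 rad the paraxial model is moot
    theta_hi = 1.5
    if trans(theta_hi) > clip_threshold or walk_per_rad == 0.0:
        vignette_d = math.inf
    else:
        theta_clip = optimize.brentq(lambda t: trans(t) - clip_threshold, 0.0, theta_hi)
        vignette_d = 2.0 * scale * theta_clip
    if round_d <= vignette_d:
        return FovReport(square, round_d, vignette_d, round_d, "mirror", clip_threshold)
    return FovReport(square, round_d, vignette_d, vignette_d, "vignetting", clip_threshold)


def field_curvature_sagitta(
    config: OpticalConfig, fov_diameter_mm: float | None = None
) -> float:
    """Axial focus difference centre minus edge, in micrometres (>= 0).

    Evaluates :func:`focus_solution` z at the field centre and at the edge
    radius (half the supplied field diameter, else the usable field), with
    the convention that edges focus closer to the objective.
    """
    if fov_diameter_mm is None:
        fov_diameter_mm = fov_diameter(config).usable_diameter_mm
    r_mm = fov_diameter_mm / 2.0
    scale = _lateral_mm_per_rad(config)
    theta_deg = math.degrees(r_mm / scale)
    # evaluate irrespective of the calibrated mirror range
    cfg = replace(config, mirrors=replace(config.mirrors, max_optical_half_angle_deg=None))
    z_centre = focus_solution(cfg).focus_point_um[2]
    z_edge = focus_solution(cfg, theta_deg, 0.0).focus_point_um[2]
    return z_centre - z_edge


# ---------------------------------------------------------------------------
# ETL


def etl_current_to_focus_shift(config: OpticalConfig, current_mA: float) -> float:
    """Axial plane shift in micrometres for an ETL drive current.

    Positive current converges the beam and (for the nTC trains) pulls the
    plane toward the objective, i.e. a negative shift in the
    away-from-objective z convention; the printed plane elevations quote the
    magnitude.
    """
    if abs(current_mA) > config.etl.max_current_mA:
        raise ValueError("current beyond max_current")
    power = config.etl.diopter_per_mA * current_mA
    if power == 0.0:
        return 0.0
    z1 = focus_solution(config, etl_power_dpt=power).focus_point_um[2]
    z0 = focus_solution(config).focus_point_um[2]
    return z1 - z0


# ---------------------------------------------------------------------------
# Calibration

_OBSERVABLE_PARAM = {
    "dl_square_fov_mm": "max_half_angle_deg",
    "dl_round_fov_mm": "max_half_angle_deg",
    "ntc_fov_mm": "max_half_angle_deg",
    "dl_psf_axial_um": "waist_radius_mm",
    "dl_psf_lateral_um": "waist_radius_mm",
    "etl_shift_um_at_50mA": "diopter_per_mA",
}

_PARAM_BOUNDS = {
    "waist_radius_mm": (0.05, 10.0),
    "max_half_angle_deg": (0.05, 30.0),
    "diopter_per_mA": (1e-4, 1.0),
}

# fixed initial guesses; the mirror angle starts small so field-of-view
# observables begin in the mirror-limited (non-saturated) regime
_PARAM_X0 = {
    "waist_radius_mm": 1.0,
    "max_half_angle_deg": 1.0,
    "diopter_per_mA": 0.05,
}


def _apply_params(config: OpticalConfig, params: dict[str, float]) -> OpticalConfig:
    cfg = config
    if "waist_radius_mm" in params:
        cfg = replace(cfg, input_beam=replace(cfg.input_beam, waist_radius_mm=params["waist_radius_mm"]))
    if "max_half_angle_deg" in params:
        cfg = replace(cfg, mirrors=replace(cfg.mirrors, max_optical_half_angle_deg=params["max_half_angle_deg"]))
    if "diopter_per_mA" in params:
        cfg = replace(cfg, etl=replace(cfg.etl, diopter_per_mA=params["diopter_per_mA"]))
    return cfg


def _predict_observable(config: OpticalConfig, name: str) -> float:
    wavelength = config.input_beam.wavelength_nm
    if name == "dl_square_fov_mm":
        return fov_diameter(_retrain(config, "DL")).mirror_limited_square_mm
    if name == "dl_round_fov_mm":
        return fov_diameter(_retrain(config, "DL")).mirror_limited_diameter_mm
    if name == "ntc_fov_mm":
        return fov_diameter(config).usable_diameter_mm
    if name == "dl_psf_axial_um":
        return predict_psf(_retrain(config, "DL")).axial_fwhm_um
    if name == "dl_psf_lateral_um":
        return predict_psf(_retrain(config, "DL")).lateral_fwhm_um
    if name == "etl_shift_um_at_50mA":
        cfg = config if config.preset != "DL" else _retrain(config, "nTC1", 100.0)
        return abs(etl_current_to_focus_shift(cfg, 50.0))
    raise ValueError(f"unknown observable {name!r} (λ={wavelength} nm path)")


def _retrain(config: OpticalConfig, preset: str, lens_distance_mm: float | None = None) -> OpticalConfig:
    if config.preset == preset and (
        lens_distance_mm is None or lens_distance_mm == config.movable_lens_distance_mm
    ):
        return config
    return replace(
        config,
        preset=preset,
        elements=_train_elements(preset, lens_distance_mm),
        movable_lens_distance_mm=None if preset == "DL" else (lens_distance_mm or 5.0),
    )


def calibrate(
    config: OpticalConfig,
    observables: Iterable[tuple[str, float]],
    fit_params: Sequence[str] | None = None,
) -> CalibrationResult:
    """Anchor the model's free parameters to measured observables.

    ``observables`` is an iterable of ``(name, value)`` pairs; duplicate
    (even contradictory) entries are legal and surface as residuals rather
    than being silently averaged into success.  ``fit_params`` defaults to
    every parameter that the supplied observables constrain.  The fit is a
    deterministic least-squares from fixed initial guesses.
    """
    obs = list(observables)
    if not obs:
        raise ValueError("empty observable list")
    for name, _ in obs:
        if name not in _OBSERVABLE_PARAM:
            raise ValueError(
                f"unknown observable {name!r}; expected one of {sorted(_OBSERVABLE_PARAM)}"
            )
    constrained = {_OBSERVABLE_PARAM[name] for name, _ in obs}
    if fit_params is None:
        params = sorted(constrained)
    else:
        params = list(fit_params)
        missing = [p for p in params if p not in constrained]
        if missing:
            raise ValueError(
                "observables insufficient to constrain parameter(s): " + ", ".join(missing)
            )
    # ETL gain calibration needs the waist and angle fixed first when they
    # are co-fitted; least_squares handles the joint problem directly.
    x0 = np.array([_PARAM_X0[p] for p in params])
    lo = np.array([_PARAM_BOUNDS[p][0] for p in params])
    hi = np.array([_PARAM_BOUNDS[p][1] for p in params])

    def residual(x: np.ndarray) -> np.ndarray:
        cfg = _apply_params(config, dict(zip(params, x)))
        out = []
        for name, value in obs:
            pred = _predict_observable(cfg, name)
            out.append((pred - value) / max(abs(value), 1e-12))
        return np.asarray(out)

    res = optimize.least_squares(residual, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fitted = dict(zip(params, (float(v) for v in res.x)))
    cfg = _apply_params(config, fitted)
    residuals = {}
    for name, value in obs:
        key = name
        i = 2
        while key in residuals:  # keep contradictory duplicates visible
            key = f"{name}#{i}"
            i += 1
        residuals[key] = _predict_observable(cfg, name) - value
    return CalibrationResult(fitted=fitted, residuals=residuals, config=cfg, cost=float(res.cost))


# ---------------------------------------------------------------------------
# Reporting


def optics_report(config: OpticalConfig) -> dict:
    """JSON-ready summary of a configuration (units embedded per field)."""
    sol = focus_solution(config)
    psf = predict_psf(config)
    fov = fov_diameter(config)
    sag = field_curvature_sagitta(config)
    ifp = sol.ifp
    return {
        "preset": config.preset,
        "movable_lens_distance": {"value": config.movable_lens_distance_mm, "units": "mm"},
        "focus_z": {"value": sol.focus_point_um[2], "units": "um"},
        "focal_distance": {"value": sol.focal_distance_mm, "units": "mm"},
        "effective_na": {"value": sol.effective_na, "units": "dimensionless"},
        "psf_lateral_fwhm": {"value": psf.lateral_fwhm_um, "units": "um"},
        "psf_axial_fwhm": {"value": psf.axial_fwhm_um, "units": "um"},
        "fov_mirror_square": {"value": fov.mirror_limited_square_mm, "units": "mm"},
        "fov_mirror_round": {"value": fov.mirror_limited_diameter_mm, "units": "mm"},
        "fov_vignette": {"value": fov.vignette_limited_diameter_mm, "units": "mm"},
        "fov_usable": {"value": fov.usable_diameter_mm, "units": "mm"},
        "fov_binding_limit": fov.binding_limit,
        "field_curvature_sagitta": {"value": sag, "units": "um"},
        "ifp": {
            "value": None if ifp.collimated else ifp.relative_to_tube_lens_mm,
            "units": "mm relative to tube lens",
            "collimated": ifp.collimated,
            "label": ifp.label,
        },
        "vignetting_fraction": {"value": sol.vignetting_fraction, "units": "fraction"},
        "wavelength": {"value": config.input_beam.wavelength_nm, "units": "nm"},
    }
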