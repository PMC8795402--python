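"""Synthetic samples and simulated acquisitions.

Phantoms are collections of spherical emitters — sub-resolution fluorescent
beads (0.175 um), or somata with species-typical diameters (fruit-fly
larva < 5 um, zebrafish larva 5–10 um, mouse cortex ~20 um) — optionally
carrying calcium-like activity traces.  Rendering evaluates, for every
pixel of a scan pattern, the overlap between each emitter and the
two-photon excitation volume centred on that pixel's focus point, so PSF
size, field curvature, per-line z-profiles and vignetting all shape the
simulated image.

The excitation volume is a squared-intensity 3D Gaussian whose FWHMs come
from the optical model.  The emitter–excitation overlap uses an analytic
Gaussian-blob approximation of the uniform sphere (matched volume and
per-axis variance R^2/5), with a brute-force numeric integral available as
a cross-check.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import OpticalConfig, focus_solution, predict_psf
from .scan import ScanPattern, apply_z_profile, timing_report

__all__ = [
    "Emitter",
    "Phantom",
    "ActivityModel",
    "AcquiredData",
    "make_phantom",
    "render_scan",
    "render_zstack",
    "render_side_profile",
    "render_timeseries",
    "sphere_gaussian_overlap",
    "sphere_gaussian_overlap_numeric",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

SOMA_DIAMETER_RANGES_UM = {
    "fly_somata": (2.0, 5.0),
    "zebrafish_somata": (5.0, 10.0),
    "mouse_somata": (15.0, 25.0),
}
BEAD_DIAMETER_UM = 0.175
BEAD_DIAMETER_SD_UM = 0.005


@dataclass(frozen=True)
class Emitter:
    centre_um: tuple[float, float, float]
    diameter_um: float
    brightness: float = 1.0
    activity_trace_id: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")


@dataclass(frozen=True)
class Phantom:
    bounds_um: tuple[float, float, float]
    emitters: tuple[Emitter, ...]
    background: float = 0.0
    preset: str = "beads"
    seed: int | None = None


@dataclass(frozen=True)
class ActivityModel:
    """Calcium-like activity: instantaneous rise, exponential decay."""

    event_rate_hz: float = 0.0
    stimulus_times_s: tuple[float, ...] = ()
    response_probability: float = 1.0
    tau_s: float = 0.5
    amplitude: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if not 0.0 <= self.response_probability <= 1.0:
            raise ValueError("response probability must lie in [0, 1]")


@dataclass(frozen=True)
class AcquiredData:
    frames: np.ndarray  # (frame, line, pixel)
    pixel_size_um: tuple[float, float]
    z_step_um: float
    frame_period_s: float
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phantom generation


def make_phantom(
    preset: str = "beads",
    count: int = 10,
    volume_um: tuple[float, float, float] = (30.0, 30.0, 10.0),
    seed: int = 0,
    brightness: float = 1.0,
    background: float = 0.0,
) -> Phantom:
    """Deterministic synthetic sample.

    ``volume_um`` is centred on the origin of the sample frame; ``beads``
    draws 0.175 +/- 0.005 um spheres, the soma presets draw diameters
    uniformly from the species-typical ranges, and ``uniform_slab`` lays a
    dense emitter lattice suited to brightness profiling.
    """
    rng = np.random.default_rng(seed)
    hx, hy, hz = (v / 2.0 for v in volume_um)
    emitters: list[Emitter] = []
    if preset == "uniform_slab":
        pitch = 2.0
        xs = np.arange(-hx + pitch / 2, hx, pitch)
        ys = np.arange(-hy + pitch / 2, hy, pitch)
        for x in xs:
            for y in ys:
                emitters.append(Emitter((float(x), float(y), 0.0), pitch, brightness))
    else:
        if preset == "beads":
            diam = rng.normal(BEAD_DIAMETER_UM, BEAD_DIAMETER_SD_UM, count)
            diam = np.clip(diam, 0.05, None)
        elif preset in SOMA_DIAMETER_RANGES_UM:
            lo, hi = SOMA_DIAMETER_RANGES_UM[preset]
            diam = rng.uniform(lo, hi, count)
        else:
            raise ValueError(f"unknown phantom preset {preset!r}")
        pos = rng.uniform(
            [-hx, -hy, -hz], [hx, hy, hz], size=(count, 3)
        )
        for i in range(count):
            emitters.append(
                Emitter(tuple(float(c) for c in pos[i]), float(diam[i]), brightness, activity_trace_id=i)
            )
    return Phantom(
        bounds_um=volume_um,
        emitters=tuple(emitters),
        background=background,
        preset=preset,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Emitter–excitation overlap


def sphere_gaussian_overlap(
    delta_um: np.ndarray,
    radius_um: float,
    sigma_um: tuple[float, float, float],
) -> np.ndarray:
    """Analytic (Gaussian-blob) overlap of a uniform sphere with the
    excitation Gaussian.

    ``delta_um`` is (..., 3) displacement between sphere centre and the
    excitation centre.  Returns the integral of the unit-peak excitation
    profile over the sphere, i.e. dim for sub-excitation-volume objects and
    saturating for large ones, normalised per unit emitter density.
    """
    delta = np.asarray(delta_um, dtype=float)
    sig2 = np.array(sigma_um, dtype=float) ** 2
    blob2 = radius_um**2 / 5.0  # per-axis variance of a uniform sphere
    eff2 = sig2 + blob2
    vol = 4.0 / 3.0 * math.pi * radius_um**3
    norm = float(np.prod(np.sqrt(sig2 / eff2)))
    expo = -0.5 * np.sum(delta**2 / eff2, axis=-1)
    return vol * norm * np.exp(expo)


def sphere_gaussian_overlap_numeric(
    delta_um: Sequence[float],
    radius_um: float,
    sigma_um: tuple[float, float, float],
    points_per_fwhm: int = 3,
) -> float:
    """Brute-force Riemann integral of the excitation profile over the sphere."""
    step = min(min(s * _FWHM_PER_SIGMA for s in sigma_um), 2 * radius_um) / points_per_fwhm
    n = max(int(math.ceil(2 * radius_um / step)), 3)
    ax = np.linspace(-radius_um, radius_um, n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= radius_um**2
    dx, dy, dz = delta_um
    sx, sy, sz = sigma_um
    prof = np.exp(
        -0.5 * (((X + dx) / sx) ** 2 + ((Y + dy) / sy) ** 2 + ((Z + dz) / sz) ** 2)
    )
    cell = (ax[1] - ax[0]) ** 3
    return float(np.sum(prof[inside]) * cell)


# ---------------------------------------------------------------------------
# Rendering


def _pattern_geometry(config: OpticalConfig, pattern: ScanPattern):
    """Per-region pixel centres and per-line focus depths (um).

    Field curvature enters through the spherical focal cap of the optical
    model; z-profiles add the commanded tunable-lens displacement per line
    (negative command depth convention folded into the displacement sign).
    """
    sol0 = focus_solution(config)
    v_um = sol0.focal_distance_mm * 1e3
    geoms = []
    for region in pattern.regions:
        nx = region.pixels_per_line
        ny = region.n_lines
        ox, oy = region.origin_um
        ex, ey = region.extent_um
        xs = ox + (np.arange(nx) + 0.5) / nx * ex - ex / 2.0
        ys = oy + (np.arange(ny) + 0.5) / ny * ey - ey / 2.0
        r2 = xs[None, :] ** 2 + ys[:, None] ** 2
        # spherical focal cap: z relative to the on-axis focus
        cap = np.sqrt(np.clip(v_um**2 - r2, 0.0, None)) - v_um
        z_cmd = apply_z_profile(region)
        z = cap + z_cmd[:, None]
        geoms.append((xs, ys, z))
    return geoms


def _psf_sigmas(config: OpticalConfig) -> tuple[float, float, float]:
    psf = predict_psf(config)
    s_lat = psf.lateral_fwhm_um / _FWHM_PER_SIGMA
    s_ax = psf.axial_fwhm_um / _FWHM_PER_SIGMA
    return (s_lat, s_lat, s_ax)


def _render_region(
    xs: np.ndarray,
    ys: np.ndarray,
    z: np.ndarray,
    emitters: Sequence[Emitter],
    sigmas: tuple[float, float, float],
    brightness_scale: np.ndarray | None,
    z_offset: float,
    background: float,
    excitation_scale: float = 1.0,
) -> np.ndarray:
    img = np.full((len(ys), len(xs)), background, dtype=float)
    sx, sy, sz = sigmas
    for k, e in enumerate(emitters):
        b = e.brightness * (1.0 if brightness_scale is None else brightness_scale[k])
        if b == 0.0:
            continue
        cx, cy, cz = e.centre_um
        radius = e.diameter_um / 2.0
        wx = 4.0 * math.sqrt(sx**2 + radius**2 / 5.0)
        wy = 4.0 * math.sqrt(sy**2 + radius**2 / 5.0)
        mx = (xs >= cx - wx) & (xs <= cx + wx)
        my = (ys >= cy - wy) & (ys <= cy + wy)
        if not mx.any() or not my.any():
            continue
        dx = xs[mx] - cx
        dy = ys[my] - cy
        dz = (z[np.ix_(my, mx)] + z_offset) - cz
        delta = np.stack(
            np.broadcast_arrays(dx[None, :], dy[:, None], dz), axis=-1
        )
        patch = sphere_gaussian_overlap(delta, radius, sigmas)
        img[np.ix_(my, mx)] += b * excitation_scale * patch
    return img


def render_scan(
    config: OpticalConfig,
    pattern: ScanPattern,
    phantom: Phantom,
    z_offset_um: float = 0.0,
) -> AcquiredData:
    """Simulate one frame of a scan pattern over a phantom.

    Pixel value = background + sum over emitters of brightness times the
    sphere–excitation overlap at that pixel's focus point.  ``z_offset_um``
    emulates a stage/objective z-step (positive moves the sampled plane
    deeper into the sample).
    """
    _check_pattern_fov(config, pattern)
    sigmas = _psf_sigmas(config)
    sol0 = focus_solution(config)
    excitation = (1.0 - sol0.vignetting_fraction) ** 2  # two-photon: squared
    geoms = _pattern_geometry(config, pattern)
    rows = [
        _render_region(
            xs, ys, z, phantom.emitters, sigmas, None, z_offset_um, phantom.background, excitation
        )
        for xs, ys, z in geoms
    ]
    frame = np.vstack(rows) if len(rows) > 1 and _same_width(rows) else rows[0]
    report = timing_report(pattern)
    return AcquiredData(
        frames=frame[None, :, :],
        pixel_size_um=_pixel_size(pattern),
        z_step_um=0.0,
        frame_period_s=report.cycle_duration_ms * 1e-3,
        provenance=_provenance(config, pattern, phantom),
    )


def render_zstack(
    config: OpticalConfig,
    pattern: ScanPattern,
    phantom: Phantom,
    z_start_um: float,
    z_step_um: float,
    n_planes: int,
) -> AcquiredData:
    """Stack of frames at stepped stage z (bead-stack acquisition)."""
    planes = [
        render_scan(config, pattern, phantom, z_offset_um=z_start_um + i * z_step_um).frames[0]
        for i in range(n_planes)
    ]
    first = render_scan(config, pattern, phantom)
    return AcquiredData(
        frames=np.stack(planes),
        pixel_size_um=first.pixel_size_um,
        z_step_um=z_step_um,
        frame_period_s=first.frame_period_s,
        provenance=first.provenance,
    )


def render_side_profile(
    config: OpticalConfig,
    pattern: ScanPattern,
    x_range_um: tuple[float, float] | None = None,
    z_range_um: tuple[float, float] | None = None,
    shape: tuple[int, int] = (160, 240),
    line_stride: int = 4,
) -> np.ndarray:
    """x–z projection of the scanned excitation, as filmed from the side.

    Sums the squared-intensity excitation profile over the slow axis while
    the pattern executes; scan-plane curvature appears directly and the
    excitation volumes tilt outward at the field edges (each Gaussian is
    oriented along the local chief ray).
    """
    sigmas = _psf_sigmas(config)
    sol0 = focus_solution(config)
    v_um = sol0.focal_distance_mm * 1e3
    geoms = _pattern_geometry(config, pattern)
    all_x = np.concatenate([xs for xs, _, _ in geoms])
    all_z = np.concatenate([z.ravel() for _, _, z in geoms])
    if x_range_um is None:
        pad = 6 * sigmas[0]
        x_range_um = (float(all_x.min() - pad), float(all_x.max() + pad))
    if z_range_um is None:
        pad = 3 * sigmas[2]
        z_range_um = (float(all_z.min() - pad), float(all_z.max() + pad))
    nz, nx = shape
    gx = np.linspace(*x_range_um, nx)
    gz = np.linspace(*z_range_um, nz)
    img = np.zeros((nz, nx))
    sx, sz = sigmas[0], sigmas[2]
    for xs, ys, z in geoms:
        for li in range(0, len(ys), line_stride):
            for pi in range(0, len(xs), max(len(xs) // 48, 1)):
                fx, fz = xs[pi], z[li, pi]
                tilt = math.asin(min(abs(fx) / v_um, 1.0)) * (1 if fx > 0 else -1)
                ct, st = math.cos(tilt), math.sin(tilt)
                dx = gx[None, :] - fx
                dz = gz[:, None] - fz
                u = ct * dx - st * dz  # across the beam
                w = st * dx + ct * dz  # along the beam
                img += np.exp(-0.5 * ((u / sx) ** 2 + (w / sz) ** 2))
    return img


def render_timeseries(
    config: OpticalConfig,
    pattern: ScanPattern,
    phantom: Phantom,
    activity: ActivityModel,
    n_frames: int,
    seed: int = 0,
) -> AcquiredData:
    """Movie of frames with emitter brightness driven by an activity model.

    Per-frame emitter brightness is base x (1 + kernel-convolved event
    train); Gaussian read noise (``noise_sd``) is added per pixel with the
    recorded seed.
    """
    rng = np.random.default_rng(seed)
    report = timing_report(pattern)
    dt = report.cycle_duration_ms * 1e-3
    n_emit = len(phantom.emitters)
    traces = activity_traces(activity, n_emit, n_frames, dt, rng)
    sigmas = _psf_sigmas(config)
    sol0 = focus_solution(config)
    excitation = (1.0 - sol0.vignetting_fraction) ** 2
    geoms = _pattern_geometry(config, pattern)
    frames = []
    for fi in range(n_frames):
        rows = [
            _render_region(
                xs, ys, z, phantom.emitters, sigmas, traces[:, fi], 0.0, phantom.background, excitation
            )
            for xs, ys, z in geoms
        ]
        frame = np.vstack(rows) if len(rows) > 1 and _same_width(rows) else rows[0]
        if activity.noise_sd > 0:
            frame = frame + rng.normal(0.0, activity.noise_sd, frame.shape)
        frames.append(frame)
    prov = _provenance(config, pattern, phantom)
    prov["activity_seed"] = seed
    return AcquiredData(
        frames=np.stack(frames),
        pixel_size_um=_pixel_size(pattern),
        z_step_um=0.0,
        frame_period_s=dt,
        provenance=prov,
    )


def activity_traces(
    activity: ActivityModel,
    n_emitters: int,
    n_frames: int,
    frame_period_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_emitters, n_frames) multiplicative brightness factors >= 1 - eps."""
    t = np.arange(n_frames) * frame_period_s
    kernel_len = min(n_frames, max(int(5 * activity.tau_s / frame_period_s), 1))
    kernel = np.exp(-np.arange(kernel_len) * frame_period_s / activity.tau_s)
    traces = np.ones((n_emitters, n_frames))
    for e in range(n_emitters):
        events = np.zeros(n_frames)
        if activity.event_rate_hz > 0:
            events += rng.poisson(activity.event_rate_hz * frame_period_s, n_frames)
        for st in activity.stimulus_times_s:
            fi = int(round(st / frame_period_s))
            if 0 <= fi < n_frames and rng.random() < activity.response_probability:
                events[fi] += 1.0
        if events.any():
            resp = np.convolve(events, kernel)[:n_frames]
            traces[e] += activity.amplitude * resp
    return traces


# ---------------------------------------------------------------------------
# helpers


def _pixel_size(pattern: ScanPattern) -> tuple[float, float]:
    r = pattern.regions[0]
    return (r.extent_um[0] / r.pixels_per_line, r.extent_um[1] / r.n_lines)


def _same_width(rows: list[np.ndarray]) -> bool:
    return len({r.shape[1] for r in rows}) == 1


def _check_pattern_fov(config: OpticalConfig, pattern: ScanPattern) -> None:
    from .optics import fov_diameter

    if config.mirrors.max_optical_half_angle_deg is None:
        return
    limit_um = fov_diameter(config).usable_diameter_mm * 1e3
    for i, r in enumerate(pattern.regions):
        reach = 2 * max(
            abs(r.origin_um[0]) + r.extent_um[0] / 2,
            abs(r.origin_um[1]) + r.extent_um[1] / 2,
        )
        if reach > limit_um:
            raise ValueError(
                f"region {i} spans {reach:.0f} um, outside the usable field "
                f"of view of {limit_um:.0f} um"
            )


def _provenance(config: OpticalConfig, pattern: ScanPattern, phantom: Phantom) -> dict:
    def digest(obj) -> str:
        return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]

    return {
        "config_hash": digest(config),
        "pattern_hash": digest(pattern),
        "phantom_seed": phantom.seed,
        "phantom_preset": phantom.preset,
        "n_emitters": len(phantom.emitters),
    }


def phantom_to_json(phantom: Phantom) -> str:
    """Serialise a phantom (emitter table) for reuse."""
    doc = {
        "bounds_um": list(phantom.bounds_um),
        "background": phantom.background,
        "preset": phantom.preset,
        "seed": phantom.seed,
        "emitters": [
            {
                "centre_um": list(e.centre_um),
                "diameter_um": e.diameter_um,
                "brightness": e.brightness,
                "activity_trace_id": e.activity_trace_id,
            }
            for e in phantom.emitters
        ],
    }
    return json.dumps(doc, indent=1)


def phantom_from_json(text: str) -> Phantom:
    doc = json.loads(text)
    emitters = tuple(
        Emitter(
            tuple(e["centre_um"]),
            e["diameter_um"],
            e.get("brightness", 1.0),
            e.get("activity_trace_id"),
        )
        for e in doc["emitters"]
    )
    return Phantom(
        bounds_um=tuple(doc["bounds_um"]),
        emitters=emitters,
        background=doc.get("background", 0.0),
        preset=doc.get("preset", "beads"),
        seed=doc.get("seed"),
    )
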