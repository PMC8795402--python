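"""Scan patterns, exact timing and line-synchronised command waveforms.

A scan pattern is an ordered list of rectangular scan regions; each region
sweeps the fast (x) mirror once per line while the slow (y) mirror steps
line by line.  A region carries a z-profile describing how the tunable-lens
command varies over its lines: flat planes, a mid-frame staircase jump,
a tilted plane (matched y- and z-movement), a "halfpipe" plane bent as a
square-root-of-cosine of the slow-axis position, or a stack of discrete
planes.  Scanning is unidirectional; the laser is blanked via the Pockels
cell during line turnarounds and the blanked transition lines that carry
the beam between random-access regions.

Frame and volume rates are exact rationals: the per-line period includes
the turnaround, so a 256-line, 1 ms/line frame runs at exactly 1/0.256 s
= 3.90625 Hz (printed as 3.91 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .optics import EtlModel, OpticalConfig, etl_current_to_focus_shift

__all__ = [
    "ZProfile",
    "ScanRegion",
    "ScanPattern",
    "TimingReport",
    "CommandWaveforms",
    "EtlCalibration",
    "build_raster",
    "build_random_access",
    "apply_z_profile",
    "timing_report",
    "emit_waveforms",
    "etl_transient",
    "depth_power_compensation",
]


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class ZProfile:
    """Per-line axial profile of one scan region (all displacements in um)."""

    kind: str = "flat"
    jump_line: int | None = None
    delta_z_um: float = 0.0
    angle_deg: float = 0.0
    peak_displacement_um: float = 0.0
    plane_offsets_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        kinds = ("flat", "staircase", "tilted", "halfpipe", "multiplane")
        if self.kind not in kinds:
            raise ValueError(f"unknown z-profile kind {self.kind!r}")
        if self.kind == "tilted" and not abs(self.angle_deg) < 90.0:
            raise ValueError("tilt angle must satisfy |angle| < 90 deg")
        if self.kind == "multiplane" and not self.plane_offsets_um:
            raise ValueError("multiplane profile requires plane offsets")

    # convenience constructors -------------------------------------------------
    @staticmethod
    def flat() -> "ZProfile":
        return ZProfile("flat")

    @staticmethod
    def staircase(jump_line: int, delta_z_um: float) -> "ZProfile":
        return ZProfile("staircase", jump_line=jump_line, delta_z_um=delta_z_um)

    @staticmethod
    def tilted(angle_deg: float) -> "ZProfile":
        return ZProfile("tilted", angle_deg=angle_deg)

    @staticmethod
    def halfpipe(peak_displacement_um: float) -> "ZProfile":
        return ZProfile("halfpipe", peak_displacement_um=peak_displacement_um)

    @staticmethod
    def multiplane(plane_offsets_um: Sequence[float]) -> "ZProfile":
        return ZProfile("multiplane", plane_offsets_um=tuple(plane_offsets_um))


@dataclass(frozen=True)
class ScanRegion:
    n_lines: int
    pixels_per_line: int
    line_period_ms: float
    origin_um: tuple[float, float] = (0.0, 0.0)  # centre of the region
    extent_um: tuple[float, float] = (300.0, 300.0)  # (x, y) size
    z_profile: ZProfile = field(default_factory=ZProfile.flat)

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.pixels_per_line < 1:
            raise ValueError("n_lines and pixels_per_line must be >= 1")
        if self.line_period_ms <= 0:
            raise ValueError("line_period_ms must be > 0")
        zp = self.z_profile
        if zp.kind == "staircase":
            if zp.jump_line is None or not (0 < zp.jump_line < self.n_lines):
                raise ValueError("staircase jump_line must lie within the line count")
        if zp.kind == "multiplane" and self.n_lines % len(zp.plane_offsets_um):
            raise ValueError("n_lines must divide evenly among the planes")


@dataclass(frozen=True)
class ScanPattern:
    regions: tuple[ScanRegion, ...]
    transition_lines: int = 0
    repeat_count: int = 1

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("pattern needs at least one region")
        if self.transition_lines < 0:
            raise ValueError("transition_lines must be >= 0")

    @property
    def active_lines(self) -> int:
        return sum(r.n_lines for r in self.regions)

    @property
    def total_lines(self) -> int:
        if len(self.regions) == 1 and self.transition_lines == 0:
            return self.active_lines
        return self.active_lines + self.transition_lines * len(self.regions)

    @property
    def line_period_ms(self) -> float:
        periods = {r.line_period_ms for r in self.regions}
        if len(periods) > 1:
            raise ValueError("regions with mixed line periods have no single period")
        return next(iter(periods))


@dataclass(frozen=True)
class TimingReport:
    frame_rate_hz: float  # full cycle including transition lines
    active_rate_hz: float  # counting active lines only (printed convention)
    per_plane_rate_hz: float | None
    total_lines: int
    active_lines: int
    transition_duration_ms: float
    cycle_duration_ms: float
    exact_frame_rate: Fraction = Fraction(0)
    exact_active_rate: Fraction = Fraction(0)


@dataclass(frozen=True)
class CommandWaveforms:
    sample_rate_hz: float
    x_galvo: np.ndarray  # fast axis, normalised scan angle in [-1, 1]
    y_galvo: np.ndarray  # slow axis
    etl_um: np.ndarray  # commanded axial displacement per sample
    pockels: np.ndarray  # transmission in [0, 1]
    line_start_samples: np.ndarray
    samples_per_line: int
    active_mask: np.ndarray  # True on active-pixel samples


@dataclass(frozen=True)
class EtlCalibration:
    """Linearised mapping between commanded diopters and plane shift."""

    um_per_dpt: float
    max_displacement_um: float

    @staticmethod
    def from_optics(config: OpticalConfig, probe_mA: float = 5.0) -> "EtlCalibration":
        dz = etl_current_to_focus_shift(config, probe_mA)
        dpt = config.etl.diopter_per_mA * probe_mA
        um_per_dpt = dz / dpt
        max_dpt = config.etl.diopter_per_mA * config.etl.max_current_mA
        return EtlCalibration(um_per_dpt=um_per_dpt, max_displacement_um=abs(um_per_dpt * max_dpt))

    def to_dpt(self, displacement_um: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(displacement_um) / self.um_per_dpt


# ---------------------------------------------------------------------------
# Builders


def build_raster(
    n_lines: int,
    pixels_per_line: int,
    line_period_ms: float,
    extent_um: tuple[float, float] = (300.0, 300.0),
    origin_um: tuple[float, float] = (0.0, 0.0),
    z_profile: ZProfile | None = None,
    fov_limit_um: float | None = None,
) -> ScanPattern:
    """Single-region unidirectional raster; the fast axis sweeps each line."""
    if fov_limit_um is not None and max(extent_um) > fov_limit_um:
        raise ValueError(
            f"extent {max(extent_um):.0f} um exceeds the configured field of view "
            f"limit of {fov_limit_um:.0f} um"
        )
    region = ScanRegion(
        n_lines,
        pixels_per_line,
        line_period_ms,
        origin_um=origin_um,
        extent_um=extent_um,
        z_profile=z_profile or ZProfile.flat(),
    )
    return ScanPattern(regions=(region,), transition_lines=0)


def build_random_access(
    regions: Sequence[ScanRegion],
    transition_lines: int = 2,
    fov_limit_um: float | None = None,
) -> ScanPattern:
    """Interleave distant regions within one cycle, paying blanked
    transition lines for each jump (two 1 ms lines suffice for
    multi-millimetre jumps on the expanded field)."""
    if len(regions) < 2:
        if len(regions) == 1:
            return ScanPattern(regions=tuple(regions), transition_lines=0)
        raise ValueError("random access needs at least one region")
    if fov_limit_um is not None:
        for i, r in enumerate(regions):
            reach = max(
                abs(r.origin_um[0]) + r.extent_um[0] / 2,
                abs(r.origin_um[1]) + r.extent_um[1] / 2,
            )
            if 2 * reach > fov_limit_um:
                raise ValueError(f"region {i} extends outside the field of view")
    return ScanPattern(regions=tuple(regions), transition_lines=transition_lines)


# ---------------------------------------------------------------------------
# Z-profiles


def apply_z_profile(
    region: ScanRegion,
    profile: ZProfile | None = None,
    etl_calibration: EtlCalibration | None = None,
) -> np.ndarray:
    """Per-line commanded axial displacement (um) for a region.

    With an :class:`EtlCalibration` the range is validated against the
    lens's reachable displacement and the command is still returned in um
    (conversion to diopters is the calibration's ``to_dpt``).
    """
    zp = profile or region.z_profile
    n = region.n_lines
    lines = np.arange(n, dtype=float)
    if zp.kind == "flat":
        z = np.zeros(n)
    elif zp.kind == "staircase":
        jump = zp.jump_line if zp.jump_line is not None else n // 2
        if not 0 < jump < n:
            raise ValueError("staircase jump_line must lie within the line count")
        z = np.where(lines < jump, 0.0, zp.delta_z_um)
    elif zp.kind == "tilted":
        y_extent = region.extent_um[1]
        frac = lines / (n - 1) if n > 1 else np.zeros(1)
        z = math.tan(math.radians(zp.angle_deg)) * (frac - 0.5) * y_extent
    elif zp.kind == "halfpipe":
        # sqrt(cosine) of the slow-axis half-period, clipped at zero:
        # zero displacement on the first/last line, peak at the centre line
        frac = lines / (n - 1) if n > 1 else np.full(1, 0.5)
        c = np.clip(np.cos(math.pi * (frac - 0.5)), 0.0, None)
        z = zp.peak_displacement_um * np.sqrt(c)
    elif zp.kind == "multiplane":
        per = n // len(zp.plane_offsets_um)
        z = np.repeat(np.asarray(zp.plane_offsets_um, dtype=float), per)
    else:  # pragma: no cover - guarded in ZProfile
        raise ValueError(zp.kind)
    if etl_calibration is not None:
        span = float(np.max(np.abs(z)))
        if span > etl_calibration.max_displacement_um:
            over = span - etl_calibration.max_displacement_um
            raise ValueError(
                f"z-profile exceeds the calibrated ETL range by {over:.1f} um"
            )
    return z


# ---------------------------------------------------------------------------
# Timing


def timing_report(pattern: ScanPattern) -> TimingReport:
    """Exact rational frame/volume rates for a pattern.

    ``active_rate_hz`` counts only the active lines (the convention under
    which the printed activity-scan rates are exact); ``frame_rate_hz``
    additionally pays the blanked transition lines of multi-region scans.
    """
    period = Fraction(pattern.line_period_ms).limit_denominator(10**9)
    active = Fraction(pattern.active_lines) * period  # ms
    total = Fraction(pattern.total_lines) * period
    exact_frame = Fraction(1000) / total
    exact_active = Fraction(1000) / active
    per_plane = None
    region0 = pattern.regions[0]
    if region0.z_profile.kind == "multiplane" and len(pattern.regions) == 1:
        # each plane is visited once per frame: plane rate == volume rate
        per_plane = float(exact_frame)
    return TimingReport(
        frame_rate_hz=float(exact_frame),
        active_rate_hz=float(exact_active),
        per_plane_rate_hz=per_plane,
        total_lines=pattern.total_lines,
        active_lines=pattern.active_lines,
        transition_duration_ms=float(pattern.transition_lines * period),
        cycle_duration_ms=float(total),
        exact_frame_rate=exact_frame,
        exact_active_rate=exact_active,
    )


# ---------------------------------------------------------------------------
# Waveforms


def emit_waveforms(
    pattern: ScanPattern,
    sample_rate_hz: float,
    turnaround_fraction: float = 0.1,
    etl_calibration: EtlCalibration | None = None,
) -> CommandWaveforms:
    """Line-synchronised command streams for mirrors, ETL and Pockels cell.

    Each line allots ``1 - turnaround_fraction`` of its period to the
    unidirectional fast-axis ramp and the remainder to the blanked
    turnaround.  The ETL command is piecewise constant per line; transition
    lines between regions are fully blanked.
    """
    if not 0.0 <= turnaround_fraction < 1.0:
        raise ValueError("turnaround_fraction must lie in [0, 1)")
    period_s = pattern.line_period_ms * 1e-3
    spl = round(sample_rate_hz * period_s)
    if spl < 2:
        raise ValueError("sample rate too low: need at least 2 samples per line")
    n_lines = pattern.total_lines
    n = n_lines * spl
    x = np.zeros(n)
    y = np.zeros(n)
    etl = np.zeros(n)
    pockels = np.zeros(n)
    active_mask = np.zeros(n, dtype=bool)
    line_starts = np.arange(n_lines) * spl

    active_spl = max(int(round(spl * (1.0 - turnaround_fraction))), 1)
    if active_spl >= spl and turnaround_fraction > 0:
        active_spl = spl - 1
    ramp = np.linspace(-1.0, 1.0, active_spl)

    li = 0
    for region in pattern.regions:
        z_lines = apply_z_profile(region, etl_calibration=etl_calibration)
        ys = (
            np.linspace(-1.0, 1.0, region.n_lines)
            if region.n_lines > 1
            else np.zeros(1)
        )
        for rl in range(region.n_lines):
            s = li * spl
            x[s : s + active_spl] = ramp
            x[s + active_spl : s + spl] = 1.0  # parked during turnaround
            y[s : s + spl] = ys[rl]
            etl[s : s + spl] = z_lines[rl]
            pockels[s : s + active_spl] = 1.0
            active_mask[s : s + active_spl] = True
            li += 1
        if len(pattern.regions) > 1 or pattern.transition_lines > 0:
            for _ in range(pattern.transition_lines):
                s = li * spl
                # mirrors slew, laser blanked, ETL holds its last value
                etl[s : s + spl] = z_lines[-1]
                li += 1
    assert li == n_lines
    return CommandWaveforms(
        sample_rate_hz=sample_rate_hz,
        x_galvo=x,
        y_galvo=y,
        etl_um=etl,
        pockels=pockels,
        line_start_samples=line_starts,
        samples_per_line=spl,
        active_mask=active_mask,
    )


# ---------------------------------------------------------------------------
# ETL settling


def etl_transient(
    step_um: float,
    etl: EtlModel | None = None,
    threshold_um: float = 5.0,
    dt_ms: float = 0.001,
    horizon_ms: float | None = None,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Second-order step response of the tunable lens and its settling time.

    The lens is modelled as a linear second-order system (natural frequency
    and damping ratio from :class:`~ntcsim.optics.EtlModel`); the settling
    time is the first instant after which the position error stays below
    ``threshold_um`` forever.  Defaults settle a 150 um jump within 3 ms at
    a 5 um threshold, matching the observed decay of the drive transient.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be > 0")
    etl = etl or EtlModel()
    if step_um == 0.0:
        t = np.arange(0.0, 1.0, dt_ms)
        return 0.0, (t, np.zeros_like(t))
    wn = 2.0 * math.pi * etl.natural_frequency_hz / 1000.0  # rad per ms
    z = etl.damping_ratio
    if horizon_ms is None:
        # run until the envelope has decayed to ~1e-13 of the step
        horizon_ms = max(2.0, 30.0 / (z * wn))
    t = np.arange(0.0, horizon_ms, dt_ms)
    if z < 1.0:
        wd = wn * math.sqrt(1.0 - z * z)
        resp = 1.0 - np.exp(-z * wn * t) * (
            np.cos(wd * t) + (z / math.sqrt(1.0 - z * z)) * np.sin(wd * t)
        )
    else:  # critically damped
        resp = 1.0 - np.exp(-wn * t) * (1.0 + wn * t)
    xpos = step_um * resp
    err = np.abs(xpos - step_um)
    above = err >= threshold_um
    if not above.any():
        return 0.0, (t, xpos)
    last = int(np.nonzero(above)[0][-1])
    settle = float(t[min(last + 1, len(t) - 1)])
    return settle, (t, xpos)


# ---------------------------------------------------------------------------
# Depth-dependent power compensation


def depth_power_compensation(
    pattern: ScanPattern,
    law: Callable[[float], float],
) -> np.ndarray:
    """Per-line Pockels scale factors compensating depth-dependent loss.

    ``law`` maps a line's commanded depth (um) to a transmission scale in
    (0, 1]; blanked transition lines inherit the preceding region's final
    scale (they are dark anyway).
    """
    scales: list[float] = []
    for region in pattern.regions:
        z_lines = apply_z_profile(region)
        for zl in z_lines:
            s = float(law(float(zl)))
            if not 0.0 < s <= 1.0:
                raise ValueError(
                    f"power law returned {s!r} at depth {zl:.1f} um; must be in (0, 1]"
                )
            scales.append(s)
        if len(pattern.regions) > 1 or pattern.transition_lines > 0:
            scales.extend([scales[-1]] * pattern.transition_lines)
    return np.asarray(scales)
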