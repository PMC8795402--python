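"""Measurement procedures applied to acquired (or simulated) data.

FWHM estimation follows the bead-measurement protocol: intensity profiles
through a bead's maximum are fitted with a Gaussian plus offset and the
full width at half maximum is 2*sqrt(2 ln 2) times the fitted sigma.
Bead-stack PSF estimates aggregate at least a handful of beads as
mean +/- s.d.  Activity maps are per-pixel mean Pearson correlations with
the neighbouring pixels' time courses; traces are z-scored against their
own baseline so the y-axis reads in s.d. units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "FwhmEstimate",
    "PsfEstimate",
    "CorrelationMap",
    "TraceSet",
    "gaussian_fwhm_fit",
    "psf_from_beadstack",
    "radial_brightness",
    "activity_correlation",
    "trace_stats",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FwhmEstimate:
    fwhm: float | None
    centre: float | None = None
    amplitude: float | None = None
    offset: float | None = None
    r_squared: float | None = None
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.success and (self.fwhm is None or self.fwhm <= 0):
            raise ValueError("successful fit requires fwhm > 0")


@dataclass(frozen=True)
class PsfEstimate:
    lateral_fwhm_um: float
    axial_fwhm_um: float
    lateral_sd_um: float
    axial_sd_um: float
    n_beads: int
    per_bead: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class CorrelationMap:
    values: np.ndarray
    neighbourhood: int


@dataclass(frozen=True)
class TraceSet:
    raw: np.ndarray  # (roi, frame)
    z_scored: np.ndarray
    baseline_window: tuple[int, int]
    event_triggered_average: np.ndarray | None  # (roi, window)
    n_trials: int
    eta_window: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Gaussian FWHM


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float, off: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + off


def gaussian_fwhm_fit(x: Sequence[float], y: Sequence[float]) -> FwhmEstimate:
    """Least-squares Gaussian + offset fit of a 1D intensity profile.

    Returns an explicit failure result (never a silent number) for
    constant or non-converging profiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        return FwhmEstimate(None, success=False, message="need at least 5 samples")
    if np.ptp(y) == 0:
        return FwhmEstimate(None, success=False, message="constant profile")
    off0 = float(np.min(y))
    amp0 = float(np.max(y) - off0)
    mu0 = float(x[int(np.argmax(y))])
    above = y - off0 > amp0 / 2.0
    width0 = max((x[above].max() - x[above].min()) if above.sum() > 1 else float(np.ptp(x)) / 4, np.ptp(x) / x.size)
    sigma0 = width0 / _FWHM_PER_SIGMA
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=(amp0, mu0, sigma0, off0), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return FwhmEstimate(None, success=False, message="fit did not converge")
    amp, mu, sigma, off = popt
    sigma = abs(float(sigma))
    if sigma == 0 or amp <= 0:
        return FwhmEstimate(None, success=False, message="degenerate fit")
    resid = y - _gaussian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return FwhmEstimate(
        fwhm=_FWHM_PER_SIGMA * sigma,
        centre=float(mu),
        amplitude=float(amp),
        offset=float(off),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Bead-stack PSF


def psf_from_beadstack(
    stack: np.ndarray,
    pixel_size_um: float,
    z_step_um: float,
    detection_threshold: float = 5.0,
    min_beads: int = 1,
    fit_window_um: float = 1.5,
) -> PsfEstimate:
    """Estimate lateral/axial PSF FWHM from a bead z-stack.

    Beads are local 3D maxima brighter than background + ``threshold`` s.d.
    For every bead, x, y and z intensity profiles through the maximum are
    fitted with :func:`gaussian_fwhm_fit`; the lateral estimate is the mean
    of x and y.  Beads whose fit window is clipped by the stack border are
    excluded rather than mis-fitted.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a (z, y, x) stack with >= 3 planes")
    bg = float(np.median(stack))
    sd = float(np.std(stack))
    thresh = bg + detection_threshold * sd
    footprint = np.ones((3, 5, 5), dtype=bool)
    maxima = (ndimage.maximum_filter(stack, footprint=footprint) == stack) & (stack > thresh)
    coords = np.argwhere(maxima)
    if coords.size == 0:
        raise ValueError("no beads above the detection threshold")
    # merge plateau duplicates: keep brightest within a small radius
    order = np.argsort(stack[tuple(coords.T)])[::-1]
    kept: list[np.ndarray] = []
    for idx in order:
        c = coords[idx]
        if all(np.any(np.abs(c - k) > (2, 4, 4)) for k in kept):
            kept.append(c)
    lat_w = max(int(round(fit_window_um / pixel_size_um)), 4)
    results: list[tuple[float, float]] = []
    nz, ny, nx = stack.shape
    for cz, cy, cx in kept:
        if not (lat_w <= cy < ny - lat_w and lat_w <= cx < nx - lat_w and 1 <= cz < nz - 1):
            continue
        xi = np.arange(cx - lat_w, cx + lat_w + 1)
        yi = np.arange(cy - lat_w, cy + lat_w + 1)
        fx = gaussian_fwhm_fit(xi * pixel_size_um, stack[cz, cy, xi])
        fy = gaussian_fwhm_fit(yi * pixel_size_um, stack[cz, yi, cx])
        zi = np.arange(nz)
        fz = gaussian_fwhm_fit(zi * z_step_um, stack[zi, cy, cx])
        if not (fx.success and fy.success and fz.success):
            continue
        # axial profile clipped at the stack border -> exclude
        if fz.centre is None or not (z_step_um <= fz.centre <= (nz - 2) * z_step_um):
            continue
        results.append(((fx.fwhm + fy.fwhm) / 2.0, fz.fwhm))
    if len(results) < min_beads:
        raise ValueError(
            f"only {len(results)} usable bead(s); need >= {min_beads}"
        )
    lat = np.array([r[0] for r in results])
    ax = np.array([r[1] for r in results])
    return PsfEstimate(
        lateral_fwhm_um=float(lat.mean()),
        axial_fwhm_um=float(ax.mean()),
        lateral_sd_um=float(lat.std(ddof=0)),
        axial_sd_um=float(ax.std(ddof=0)),
        n_beads=len(results),
        per_bead=tuple(results),
    )


# ---------------------------------------------------------------------------
# Radial brightness


def radial_brightness(
    image: np.ndarray, n_bins: int = 32, pixel_size_um: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean brightness in annuli from the image centre to the inscribed edge.

    Returns (bin centre radii, mean brightness per annulus).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("need a 2D image")
    ny, nx = img.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx) * pixel_size_um
    r_max = min(cy, cx) * pixel_size_um
    edges = np.linspace(0.0, r_max, n_bins + 1)
    which = np.digitize(r.ravel(), edges) - 1
    vals = img.ravel()
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            means[b] = vals[sel].mean()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, means


# ---------------------------------------------------------------------------
# Activity correlation


def activity_correlation(movie: np.ndarray, neighbourhood: int = 8) -> CorrelationMap:
    """Mean Pearson correlation of each pixel's time course with its neighbours.

    ``neighbourhood`` is 4- or 8-connectivity.  Pixels (or neighbours) with
    zero temporal variance contribute correlation 0 by convention.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 3:
        raise ValueError("need a (frame, y, x) movie with >= 3 frames")
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    t, ny, nx = movie.shape
    m = movie - movie.mean(axis=0, keepdims=True)
    sd = m.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(m)
    z[:, ok] = m[:, ok] / sd[ok]
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighbourhood == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    acc = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    for dy, dx in offsets:
        ys = slice(max(dy, 0), ny + min(dy, 0))
        xs = slice(max(dx, 0), nx + min(dx, 0))
        ys2 = slice(max(-dy, 0), ny + min(-dy, 0))
        xs2 = slice(max(-dx, 0), nx + min(-dx, 0))
        corr = (z[:, ys, xs] * z[:, ys2, xs2]).mean(axis=0)
        valid = ok[ys, xs] & ok[ys2, xs2]
        acc[ys, xs] += np.where(valid, corr, 0.0)
        cnt[ys, xs] += 1
    values = np.where(ok, acc / np.maximum(cnt, 1), 0.0)
    values = np.clip(values, -1.0, 1.0)
    return CorrelationMap(values=values, neighbourhood=neighbourhood)


# ---------------------------------------------------------------------------
# Trace statistics


def trace_stats(
    movie: np.ndarray,
    rois: Sequence[np.ndarray],
    baseline_window: tuple[int, int],
    event_frames: Sequence[int] = (),
    eta_window: tuple[int, int] = (-2, 8),
) -> TraceSet:
    """ROI traces, z-scored against their own baseline, plus event averages.

    ``rois`` are boolean masks over (y, x).  The z-score uses the baseline
    window's mean and s.d.; an event-triggered average (ETA) aligns windows
    of ``eta_window`` frames around each event and reports the trial count.
    """
    movie = np.asarray(movie, dtype=float)
    t = movie.shape[0]
    b0, b1 = baseline_window
    if not (0 <= b0 < b1 <= t):
        raise ValueError("baseline window must be a non-empty frame range")
    traces = []
    for roi in rois:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != movie.shape[1:]:
            raise ValueError("ROI mask shape must match the frame shape")
        if not roi.any():
            raise ValueError("empty ROI")
        traces.append(movie[:, roi].mean(axis=1))
    raw = np.asarray(traces)
    base = raw[:, b0:b1]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline variance in at least one ROI")
    z = (raw - mu) / sd
    eta = None
    n_trials = 0
    if event_frames:
        w0, w1 = eta_window
        windows = []
        for ev in event_frames:
            if 0 <= ev + w0 and ev + w1 <= t:
                windows.append(z[:, ev + w0 : ev + w1])
        n_trials = len(windows)
        if n_trials:
            eta = np.mean(windows, axis=0)
    return TraceSet(
        raw=raw,
        z_scored=z,
        baseline_window=baseline_window,
        event_triggered_average=eta,
        n_trials=n_trials,
        eta_window=eta_window if event_frames else None,
    )
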