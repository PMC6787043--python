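"""Raw-to-analyzable spectral preprocessing.

The chain mirrors what tissue Raman practice requires before any statistics:

1. **Despiking** — cosmic-ray hits are single/few-channel detector events far
   above the local signal; channels deviating from a running median by more
   than ``z_threshold`` robust (MAD-scaled) standard deviations are replaced
   by the local median.
2. **Fluorescence baseline estimation** — an iterative shifted-window spline:
   low-quantile anchor points are extracted from overlapping windows (the
   anchor keeps the *location* of the low-intensity sample, so sloped or
   curved backgrounds are tracked without the downward bias a center-anchored
   quantile would introduce), a cubic spline is fit through them, and anchors
   are re-estimated from the points at or below the current spline until the
   baseline stops moving.
3. **Area normalization** — the corrected spectrum is scaled so its
   trapezoidal integral over the instrument's normalization region equals 1:
   400-1800 cm^-1 for the 1064 nm system, 400-3200 cm^-1 for the 785 nm one.

Negative post-subtraction intensities are clipped at zero so the
normalization integral stays positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d, median_filter

from .errors import (
    DegenerateSpectrumError,
    InsufficientSupportError,
    ShapeError,
    WindowError,
)
from .spectra import RamanSpectrum


@dataclass
class PreprocessConfig:
    """Defaults for the full preprocessing chain."""

    despike_window: int = 7
    z_threshold: float = 10.0
    rel_threshold: float = 0.5
    window_width: float = 200.0  # cm^-1
    step: float = 100.0  # cm^-1
    quantile: float = 0.10
    max_iter: int = 20
    tol: float = 1e-3
    region: tuple[float, float] | None = None  # None -> instrument default


# -- cosmic-ray filtering ---------------------------------------------------

def despike(
    s: RamanSpectrum,
    window: int = 7,
    z_threshold: float = 10.0,
    rel_threshold: float = 0.5,
) -> RamanSpectrum:
    """Replace cosmic-ray spike channels by the local running median.

    A channel is a spike when its deviation from the running median exceeds
    ``z_threshold`` robust (MAD-scaled) standard deviations AND
    ``rel_threshold`` times the local median level.  The second condition
    encodes the physics that separates detector hits from chemistry: a
    cosmic-ray event rivals or dwarfs the entire local signal (a 10x-local
    spike deviates by 9x the local level), while the top of a genuine Raman
    band deviates from the running median by only a modest fraction of the
    band amplitude — far above noise, far below the local level.
    """
    s.require_stage("raw")
    if window < 3 or window % 2 == 0:
        raise WindowError("despike window must be odd and >= 3")
    if window >= s.shift.size:
        raise WindowError(
            f"despike window ({window}) must be smaller than the spectrum "
            f"({s.shift.size} channels)"
        )
    med = median_filter(s.intensity, size=window, mode="nearest")
    resid = s.intensity - med
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale <= 0:
        # noise-free data: anchor the z-guard on the structural residual of
        # the smooth spectrum (sharp peak tops / valley floors) so curvature
        # extrema are not flagged; the 99.5th percentile is immune to the
        # few channels an actual spike occupies
        scale = 1.4826 * float(np.quantile(np.abs(resid), 0.995))
    if scale <= 0:
        scale = np.finfo(float).tiny
    floor = 1e-12 * float(np.max(np.abs(s.intensity), initial=0.0))
    spikes = (
        (np.abs(resid) > z_threshold * scale)
        & (np.abs(resid) > rel_threshold * np.maximum(med, np.finfo(float).tiny))
        & (np.abs(resid) > floor)
    )
    cleaned = np.where(spikes, med, s.intensity)
    out = s.replace(intensity=cleaned)
    out.advance_stage("despiked")
    out.meta["despiked_channels"] = int(spikes.sum())
    return out


# -- baseline estimation ----------------------------------------------------

def _window_anchor(
    x: np.ndarray, y: np.ndarray, lo: float, hi: float, quantile: float
) -> tuple[float, float] | None:
    """Low-quantile anchor of one window: median position/value of the
    lowest-``quantile`` fraction of samples (at least one)."""
    mask = (x >= lo) & (x <= hi)
    n = int(mask.sum())
    if n == 0:
        return None
    xs, ys = x[mask], y[mask]
    k = max(1, int(np.ceil(quantile * n)))
    idx = np.argpartition(ys, k - 1)[:k]
    return float(np.median(xs[idx])), float(np.median(ys[idx]))


def _edge_anchor(
    x: np.ndarray,
    y: np.ndarray,
    lo: float,
    hi: float,
    at: float,
    keep: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Anchor at an axis end: a least-squares line through the window's
    retained (near-baseline) points, evaluated at the end channel.  Plain
    quantile anchors sit inside the window, which leaves the end channels to
    extrapolation — fatal where the fluorescence background rises steeply."""
    mask = (x >= lo) & (x <= hi)
    if int(mask.sum()) < 3:
        return None
    if keep is not None and int((mask & keep).sum()) >= 3:
        xs, ys = x[mask & keep], y[mask & keep]
    else:
        # lower half of the window's samples
        xs, ys = x[mask], y[mask]
        k = max(3, xs.size // 2)
        idx = np.argpartition(ys, min(k, ys.size) - 1)[:k]
        xs, ys = xs[idx], ys[idx]
    coef = np.polyfit(xs, ys, 1)
    return float(at), float(np.polyval(coef, at))


def _fit_spline(anchors: list[tuple[float, float]], x: np.ndarray) -> np.ndarray:
    ax = np.array([a[0] for a in anchors])
    ay = np.array([a[1] for a in anchors])
    order = np.argsort(ax)
    ax, ay = ax[order], ay[order]
    # merge anchors that collide in x
    keep_x: list[float] = []
    keep_y: list[float] = []
    for xi, yi in zip(ax, ay):
        if keep_x and xi - keep_x[-1] < 1e-9:
            keep_y[-1] = min(keep_y[-1], yi)
        else:
            keep_x.append(xi)
            keep_y.append(yi)
    ax, ay = np.array(keep_x), np.array(keep_y)
    spline = CubicSpline(ax, ay, bc_type="natural")
    out = np.empty_like(x)
    inside = (x >= ax[0]) & (x <= ax[-1])
    out[inside] = spline(x[inside])
    # linear extrapolation with the end slopes: cubic extrapolation of a
    # natural spline diverges quickly outside the anchor range
    left_slope = float(spline(ax[0], 1))
    right_slope = float(spline(ax[-1], 1))
    out[x < ax[0]] = ay[0] + left_slope * (x[x < ax[0]] - ax[0])
    out[x > ax[-1]] = ay[-1] + right_slope * (x[x > ax[-1]] - ax[-1])
    return out


def estimate_baseline(
    s: RamanSpectrum,
    window_width: float = 200.0,
    step: float = 100.0,
    quantile: float = 0.10,
    max_iter: int = 20,
    tol: float = 1e-3,
) -> np.ndarray:
    """Estimate the fluorescence baseline of a despiked spectrum.

    Returns a vector on the spectrum's axis, everywhere finite, clipped to
    the running upper envelope of the data.  Warns (but proceeds) on raw
    input — spikes corrupt the quantile anchors — and on non-convergence.
    """
    if s.stage == "raw":
        warnings.warn(
            "estimating a baseline on a raw (not despiked) spectrum; cosmic "
            "rays may bias the anchors",
            stacklevel=2,
        )
    else:
        s.require_stage("despiked")
    if window_width < 4.0 * s.profile.resolution:
        raise WindowError(
            f"window_width ({window_width}) must be >= 4x the instrument "
            f"resolution ({s.profile.resolution})"
        )
    x, y = s.shift, s.intensity
    span = x[-1] - x[0]
    starts = np.arange(x[0], x[-1] - window_width + 1e-9, step)
    if len(starts) == 0 or span < window_width:
        raise InsufficientSupportError("spectrum narrower than one window")
    windows = [(lo, lo + window_width) for lo in starts]
    if windows[-1][1] < x[-1] - 1e-9:
        windows.append((x[-1] - window_width, x[-1]))
    if len(windows) < 4:
        raise InsufficientSupportError(
            f"only {len(windows)} baseline windows; at least 4 required"
        )
    # short edge windows pin the spline at the exact axis ends, where plain
    # extrapolation would miss a steeply rising background
    edge = max(step / 2.0, 4.0 * s.profile.resolution)
    edge_windows = [(x[0], x[0] + edge, x[0]), (x[-1] - edge, x[-1], x[-1])]

    def build_anchors(keep: np.ndarray | None) -> list[tuple[float, float]]:
        anchors: list[tuple[float, float]] = []
        for lo, hi, at in edge_windows:
            a = _edge_anchor(x, y, lo, hi, at, keep=keep)
            if a is not None:
                anchors.append(a)
        for lo, hi in windows:
            if keep is None:
                a = _window_anchor(x, y, lo, hi, quantile)
            else:
                mask = (x >= lo) & (x <= hi) & keep
                if int(mask.sum()) >= 3:
                    a = (float(np.median(x[mask])), float(np.median(y[mask])))
                else:
                    a = _window_anchor(x, y, lo, hi, quantile)
            if a is not None:
                anchors.append(a)
        return anchors

    baseline = _fit_spline(build_anchors(None), x)

    converged = False
    for it in range(max_iter):
        resid = y - baseline
        neg = resid[resid < 0]
        if neg.size >= 8:
            sigma = 1.4826 * float(np.median(-neg))
        else:
            sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        sigma = max(sigma, np.finfo(float).tiny)
        refit = _fit_spline(build_anchors(y <= baseline + sigma), x)
        # decaying relaxation: anchor sets of successive iterates flip
        # borderline channels, so the raw map oscillates; averaging the
        # trajectory makes it converge
        new_baseline = baseline + (refit - baseline) / (0.5 * it + 1.0)
        scale = float(np.max(baseline) - np.min(baseline)) + np.finfo(float).eps
        change = float(np.max(np.abs(new_baseline - baseline))) / scale
        baseline = new_baseline
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "baseline estimation did not converge; returning best iterate",
            stacklevel=2,
        )
    # never exceed the running upper envelope of the spectrum
    envelope = maximum_filter1d(y, size=9, mode="nearest")
    return np.minimum(baseline, envelope)


def subtract_baseline(s: RamanSpectrum, baseline: np.ndarray) -> RamanSpectrum:
    """Subtract a baseline vector, clipping negatives at zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise ShapeError(
            f"baseline length {baseline.size} != spectrum length {s.intensity.size}"
        )
    out = s.replace(intensity=np.clip(s.intensity - baseline, 0.0, None))
    if s.stage != "baseline_corrected":
        out.advance_stage("baseline_corrected")
    return out


# -- area normalization -----------------------------------------------------

def region_integral(s: RamanSpectrum, region: tuple[float, float]) -> float:
    """Trapezoidal integral of the spectrum over a shift region."""
    lo, hi = region
    mask = (s.shift >= lo) & (s.shift <= hi)
    if int(mask.sum()) < 2:
        raise DegenerateSpectrumError(
            f"fewer than 2 channels inside region ({lo}, {hi})"
        )
    return float(np.trapezoid(s.intensity[mask], s.shift[mask]))


def area_normalize(
    s: RamanSpectrum, region: tuple[float, float] | None = None
) -> RamanSpectrum:
    """Scale a baseline-corrected spectrum to unit area over ``region``.

    The default region comes from the instrument profile.  After this stage
    the trapezoidal integral over the region is 1 to within 1e-9.
    """
    s.require_stage("baseline_corrected")
    if region is None:
        region = s.profile.normalization_region
    integral = region_integral(s, region)
    if integral <= 0:
        raise DegenerateSpectrumError(
            f"normalization integral over {region} is {integral:g}; "
            "must be positive"
        )
    out = s.replace(intensity=s.intensity / integral)
    out.advance_stage("normalized")
    out.meta["normalization_region"] = region
    out.meta["normalization_integral"] = integral
    return out


# -- full chain -------------------------------------------------------------

def preprocess_pipeline(
    s: RamanSpectrum, cfg: PreprocessConfig | None = None
) -> RamanSpectrum:
    """despike -> estimate+subtract baseline -> area-normalize one spectrum."""
    cfg = cfg or PreprocessConfig()
    s.require_stage("raw")
    d = despike(
        s,
        window=cfg.despike_window,
        z_threshold=cfg.z_threshold,
        rel_threshold=cfg.rel_threshold,
    )
    baseline = estimate_baseline(
        d,
        window_width=cfg.window_width,
        step=cfg.step,
        quantile=cfg.quantile,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    c = subtract_baseline(d, baseline)
    out = area_normalize(c, region=cfg.region)
    out.meta["preprocess"] = {
        "despiked_channels": d.meta.get("despiked_channels", 0),
        "window_width": cfg.window_width,
        "step": cfg.step,
        "quantile": cfg.quantile,
    }
    return out


def preprocess_cohort(
    spectra: list[RamanSpectrum], cfg: PreprocessConfig | None = None
) -> list[RamanSpectrum]:
    return [preprocess_pipeline(s, cfg) for s in spectra]
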