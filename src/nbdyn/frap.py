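"""FRAP recovery-curve extraction, normalization, fitting and summary rates.

The percentage-recovery convention: with F_pre the mean background-
subtracted bleach-ROI intensity over the pre-bleach frames and F_post the
first post-bleach frame,

    recovery_pct(t) = 100 * (F(t) - F_post) / (F_pre - F_post),

so the first post-bleach frame maps to exactly 0 and full recovery to 100.
The fitted maximum recovery is the plateau A of a single-exponential
R(t) = A (1 - exp(-k t)); the initial rate is the average recovery rate
over the first 15 s post-bleach, computed as the origin-anchored
least-squares slope through the first three recovery points
(t = 5, 10, 15 s): sum(t_i R_i) / sum(t_i^2), in %/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import Movie
from .errors import err
from .rois import RoiSpec

INITIAL_RATE_WINDOW_S = 15.0


@dataclass
class FrapCurve:
    """Normalized percentage-recovery time course for one bleached ROI."""

    times: np.ndarray  # s post-bleach; 0 at the first post-bleach frame
    recovery_pct: np.ndarray
    raw_roi: np.ndarray  # background-subtracted ROI mean per movie frame
    raw_background: np.ndarray
    prebleach_level: float
    postbleach_level: float
    raw_reference: np.ndarray | None = None


@dataclass
class FrapFit:
    """Fitted exchange-dynamics summary for one recovery curve."""

    max_recovery_pct: float  # plateau; 100 = full recovery
    rate_k: float  # 1/s
    initial_rate: float  # %/s over the first 15 s
    fit_rss: float
    converged: bool
    flagged: bool = False  # plateau outside the plausible [0, 110] band


def _roi_means(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return frames[:, mask].mean(axis=1)


def extract_recovery_curve(
    movie: Movie,
    bleach_roi: RoiSpec,
    bleach_frame: int,
    background_roi: RoiSpec,
    reference_roi: RoiSpec | None = None,
) -> FrapCurve:
    """Measure and normalize the recovery of a bleached ROI.

    Background is subtracted frame-by-frame; when a reference ROI is given
    the trace is additionally divided by the (background-subtracted)
    reference trace normalized to its own pre-bleach mean, which divides
    out acquisition photobleaching.  The bleach frame itself is excluded;
    t = 0 at the first frame after it.
    """
    if bleach_frame < 1:
        raise err("invalid_bleach_frame", "need at least one pre-bleach frame")
    if bleach_frame + 2 >= movie.n_frames:
        raise err("invalid_bleach_frame", "need at least two post-bleach frames")
    shape = movie.frame_shape
    bmask = bleach_roi.rasterize(shape)
    gmask = background_roi.rasterize(shape)
    if (bmask & gmask).any():
        raise err("roi_overlap", "bleach and background ROIs overlap")
    frames = movie.frames.astype(np.float64)
    bg = _roi_means(frames, gmask)
    roi = _roi_means(frames, bmask) - bg
    ref = None
    if reference_roi is not None:
        rmask = reference_roi.rasterize(shape)
        if (rmask & bmask).any():
            raise err("roi_overlap", "bleach and reference ROIs overlap")
        ref = _roi_means(frames, rmask) - bg
        pre_ref = ref[:bleach_frame].mean()
        if pre_ref <= 0:
            raise err("invalid_config", "reference ROI has no signal above background")
        roi = roi / np.maximum(ref / pre_ref, 1e-9)
    else:
        warnings.warn(
            "no reference ROI given: acquisition-photobleaching correction skipped",
            stacklevel=2,
        )

    t = movie.times()
    f_pre = roi[:bleach_frame].mean()
    post = roi[bleach_frame + 1:]
    f_post = post[0]
    if f_pre <= f_post:
        raise err("no_bleach_detected", "pre-bleach level not above first post-bleach frame")
    rec = 100.0 * (post - f_post) / (f_pre - f_post)
    tt = t[bleach_frame + 1:] - t[bleach_frame + 1]
    return FrapCurve(
        times=tt,
        recovery_pct=rec,
        raw_roi=roi,
        raw_background=bg,
        prebleach_level=float(f_pre),
        postbleach_level=float(f_post),
        raw_reference=ref,
    )


def _single_exp(t, a, k):
    return a * (1.0 - np.exp(-k * t))


def _double_exp(t, a1, k1, a2, k2):
    return a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def fit_recovery(curve: FrapCurve, model: str = "single_exp") -> FrapFit:
    """Least-squares fit of the recovery plateau.

    ``single_exp`` (default) fits A (1 - e^{-kt}); ``double_exp`` fits the
    two-component sum and reports the total plateau and the faster rate.
    Non-convergence falls back to the mean of the last three observed
    points with ``converged=False``.
    """
    t, r = curve.times, curve.recovery_pct
    if len(t) < 4:
        raise err("insufficient_points", "need >= 4 post-bleach points to fit")
    tail = float(np.mean(r[-3:]))
    try:
        if model == "single_exp":
            p0 = (max(tail, 1.0), 0.05)
            popt, _ = curve_fit(
                _single_exp, t, r, p0=p0, bounds=([0.0, 1e-6], [500.0, 100.0]), maxfev=10000
            )
            a, k = popt
            resid = r - _single_exp(t, *popt)
        elif model == "double_exp":
            p0 = (max(tail, 1.0) / 2, 0.1, max(tail, 1.0) / 2, 0.01)
            popt, _ = curve_fit(
                _double_exp,
                t,
                r,
                p0=p0,
                bounds=([0.0, 1e-6, 0.0, 1e-6], [500.0, 100.0, 500.0, 100.0]),
                maxfev=20000,
            )
            a = popt[0] + popt[2]
            k = max(popt[1], popt[3])
            resid = r - _double_exp(t, *popt)
        else:
            raise err("invalid_config", f"unknown fit model {model!r}")
        fit = FrapFit(
            max_recovery_pct=float(a),
            rate_k=float(k),
            initial_rate=initial_rate(curve),
            fit_rss=float(np.sum(resid**2)),
            converged=True,
        )
    except RuntimeError:
        fit = FrapFit(
            max_recovery_pct=tail,
            rate_k=float("nan"),
            initial_rate=initial_rate(curve),
            fit_rss=float("nan"),
            converged=False,
        )
    fit.flagged = not (0.0 <= fit.max_recovery_pct <= 110.0)
    return fit


def initial_rate(
    curve: FrapCurve,
    window: float = INITIAL_RATE_WINDOW_S,
    method: str = "regression",
) -> float:
    """Average recovery rate over the first ``window`` seconds (%/s).

    ``regression`` (default): origin-anchored least-squares slope through
    the recovery points on the 5 s grid within the window,
    sum(t_i R_i) / sum(t_i^2) -- equal to R(15)/15 for linear data but
    robust to noise.  ``endpoint``: R(window)/window.
    """
    t, r = curve.times, curve.recovery_pct
    if t[-1] < window:
        raise err("insufficient_early_points", f"curve does not span {window} s")
    grid = np.arange(5.0, window + 1e-9, 5.0)
    if np.all(np.isin(grid, np.round(t, 6))):
        rg = np.interp(grid, t, r)
    else:
        # points merely span the grid: interpolate onto it
        if (t > 0).sum() < 3:
            raise err("insufficient_early_points", "need 3 post-bleach points within 15 s")
        rg = np.interp(grid, t, r)
    if method == "endpoint":
        return float(rg[-1] / grid[-1])
    return float(np.sum(grid * rg) / np.sum(grid**2))


def analyze_frap(
    movie: Movie,
    bleach_roi: RoiSpec,
    bleach_frame: int,
    background_roi: RoiSpec,
    reference_roi: RoiSpec | None = None,
    model: str = "single_exp",
) -> tuple[FrapCurve, FrapFit]:
    """Extraction + fit in one call."""
    curve = extract_recovery_curve(
        movie, bleach_roi, bleach_frame, background_roi, reference_roi
    )
    return curve, fit_recovery(curve, model=model)
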