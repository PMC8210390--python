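"""Pixel-wise T1 and T2 relaxometry.

T1 is estimated from saturation-recovery series with the three-parameter
model ``M(TD) = A - B * exp(-TD / T1)``, where ``M`` is the observed signal
at saturation delay ``TD`` and ``A``, ``B`` are scale factors (for an ideal
saturation-recovery experiment ``A == B``).  T2 is estimated from multi-echo
spin-echo series with the mono-exponential decay ``S(TE) = S0 * exp(-TE/T2)``.

Parametric maps apply the pixel fit to every pixel of an image stack under
an optional inclusion mask; failed pixels carry a NaN sentinel and are
excluded from ROI statistics (no inpainting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError

__all__ = [
    "RecoverySeries",
    "EchoSeries",
    "T1FitResult",
    "T2FitResult",
    "ParametricMap",
    "fit_t1_pixel",
    "fit_t1_map",
    "fit_t2_pixel",
    "fit_t2_map",
    "map_roi_stats",
]

#: Lower/upper bound on fitted T1 (ms).  Wide enough for any tissue at any
#: field strength; the bound mainly stops the solver from diverging on
#: pathological pixels.
T1_BOUNDS = (1.0, 10000.0)

SENTINEL = np.nan


def _as_stack(frames) -> np.ndarray:
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise InputError(f"expected a (n_frames, h, w) stack, got shape {arr.shape}")
    return arr


def _check_timing(times, minimum: int, name: str) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < minimum:
        raise InputError(f"need at least {minimum} {name} values, got {t.size}")
    if np.any(t <= 0):
        raise InputError(f"{name} values must be positive")
    if np.any(np.diff(t) <= 0):
        raise InputError(f"{name} values must be strictly increasing")
    return t


@dataclass
class RecoverySeries:
    """A saturation-recovery image stack with per-frame delay times.

    Parameters
    ----------
    frames : (n, h, w) array
        Signal magnitude per recovery delay.
    delays : (n,) array
        Saturation recovery delay times TD in ms, strictly increasing.
    mask : (h, w) bool array, optional
        Pixel inclusion mask; ``None`` means all pixels.
    pixel_spacing : float
        In-plane resolution in mm/pixel (metadata).
    """

    frames: np.ndarray
    delays: np.ndarray
    mask: np.ndarray | None = None
    pixel_spacing: float = 0.39

    def __post_init__(self) -> None:
        self.frames = _as_stack(self.frames)
        self.delays = _check_timing(self.delays, 3, "delay")
        if self.frames.shape[0] != self.delays.size:
            raise InputError(
                f"{self.frames.shape[0]} frames but {self.delays.size} delays"
            )
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise InputError("signal values must be finite and non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise InputError("mask shape does not match frame shape")


@dataclass
class EchoSeries:
    """A multi-echo image stack with per-frame echo times (ms)."""

    frames: np.ndarray
    echoes: np.ndarray
    mask: np.ndarray | None = None
    pixel_spacing: float = 0.39

    def __post_init__(self) -> None:
        self.frames = _as_stack(self.frames)
        self.echoes = _check_timing(self.echoes, 2, "echo")
        if self.frames.shape[0] != self.echoes.size:
            raise InputError(
                f"{self.frames.shape[0]} frames but {self.echoes.size} echoes"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise InputError("mask shape does not match frame shape")


@dataclass
class T1FitResult:
    A: float
    B: float
    T1: float
    rmse: float
    converged: bool


@dataclass
class T2FitResult:
    S0: float
    T2: float
    rmse: float
    converged: bool


@dataclass
class ParametricMap:
    """Per-pixel relaxation-time map with fit diagnostics.

    ``values`` holds the parameter in ms with NaN for pixels outside the mask
    or with failed fits; ``quality`` holds the per-pixel residual RMSE.
    """

    values: np.ndarray
    quality: np.ndarray
    kind: str  # "T1" | "T2"

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def _t1_model(params: np.ndarray, td: np.ndarray) -> np.ndarray:
    a, b, t1 = params
    return a - b * np.exp(-td / t1)


def _t1_jacobian(params: np.ndarray, td: np.ndarray) -> np.ndarray:
    _, b, t1 = params
    e = np.exp(-td / t1)
    return np.column_stack([np.ones_like(td), -e, -b * e * td / t1**2])


def _t1_linear_solve(t1: float, delays: np.ndarray, signal: np.ndarray):
    """Closed-form (A, B) and SSR at fixed T1 (the model is linear in A, B)."""
    e = np.exp(-delays / t1)
    n = delays.size
    se, se2 = e.sum(), (e * e).sum()
    sy, sey = signal.sum(), (e * signal).sum()
    det = n * se2 - se * se
    if det <= 1e-300:
        return np.nan, np.nan, np.inf
    a = (sy * se2 - se * sey) / det
    b = (se * sy - n * sey) / det
    resid = a - b * e - signal
    return a, b, float(resid @ resid)


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, iterations: int = 45) -> float:
    """Golden-section minimization of a unimodal scalar function."""
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, fd = f(c), f(d)
    for _ in range(iterations):
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - _INVPHI * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + _INVPHI * (hi - lo)
            fd = f(d)
    return 0.5 * (lo + hi)


def fit_t1_pixel(signal, delays) -> T1FitResult:
    """Fit ``M = A - B*exp(-TD/T1)`` to one pixel's recovery curve.

    Uses variable projection: A and B enter the model linearly, so the fit
    reduces to a 1-D least-squares search over T1 (coarse log-spaced grid
    bracketing followed by bounded scalar minimization), with the linear
    pair solved in closed form at each T1.  Falls back to bounded nonlinear
    least squares (analytic initialization: ``A0 = max(M)``,
    ``B0 = A0 - min(M)``, ``T1_0`` from the delay nearest 63% recovery) when
    the projected solution violates the positivity constraints.  Returns
    ``converged=False`` with NaN estimates if the curve decreases with delay
    (inconsistent with recovery) or the solver fails.
    """
    signal = np.asarray(signal, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if signal.shape != delays.shape:
        raise InputError("signal and delays have mismatched lengths")
    delays = _check_timing(delays, 3, "delay")
    if not np.all(np.isfinite(signal)):
        raise InputError("signal must be finite")

    failed = T1FitResult(SENTINEL, SENTINEL, SENTINEL, SENTINEL, False)
    span = signal.max() - signal.min()
    scale = max(abs(signal).max(), 1.0)
    # A recovery curve rises with TD; a clearly falling curve cannot be fit.
    slope = np.polyfit(delays, signal, 1)[0] if span > 0 else 0.0
    if span > 1e-9 * scale and slope < 0:
        return failed

    # variable-projection path: vectorized coarse grid, then golden-section
    grid = np.geomspace(T1_BOUNDS[0], T1_BOUNDS[1], 60)
    e = np.exp(-delays[None, :] / grid[:, None])  # (n_grid, n_samples)
    n = delays.size
    se, se2 = e.sum(axis=1), (e * e).sum(axis=1)
    sy, sey = signal.sum(), e @ signal
    det = n * se2 - se * se
    # near-singular grid points blow up harmlessly; the det mask drops them
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a_g = (sy * se2 - se * sey) / det
        b_g = (se * sy - n * sey) / det
        # SSR expanded: ||y||^2 - 2(A Σy - B Σey) + A^2 n - 2AB Σe + B^2 Σe^2
        ssr = (
            signal @ signal
            - 2 * (a_g * sy - b_g * sey)
            + a_g * a_g * n
            - 2 * a_g * b_g * se
            + b_g * b_g * se2
        )
    ssr = np.where(det > 1e-300, ssr, np.inf)
    i = int(np.argmin(ssr))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    t1 = _golden_section(lambda t: _t1_linear_solve(t, delays, signal)[2], lo, hi)
    a, b, best_ssr = _t1_linear_solve(t1, delays, signal)
    if np.isfinite(best_ssr) and a >= 0 and b >= 0 and T1_BOUNDS[0] < t1 < T1_BOUNDS[1]:
        rmse = math.sqrt(best_ssr / signal.size)
        return T1FitResult(float(a), float(b), t1, rmse, True)

    # constrained fallback
    a0 = signal.max()
    b0 = max(a0 - signal.min(), 1e-6 * scale)
    target = signal.min() + 0.632 * span
    t1_0 = float(delays[np.argmin(np.abs(signal - target))])
    t1_0 = min(max(t1_0, T1_BOUNDS[0] * 1.01), T1_BOUNDS[1] * 0.99)

    try:
        res = least_squares(
            lambda p: _t1_model(p, delays) - signal,
            x0=[a0, b0, t1_0],
            jac=lambda p: _t1_jacobian(p, delays),
            bounds=([0.0, 0.0, T1_BOUNDS[0]], [np.inf, np.inf, T1_BOUNDS[1]]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    except Exception:
        return failed
    if not res.success or not np.all(np.isfinite(res.x)):
        return failed
    a, b, t1 = res.x
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return T1FitResult(float(a), float(b), float(t1), rmse, True)


def fit_t2_pixel(signal, echoes, refine: bool = False) -> T2FitResult:
    """Estimate ``(S0, T2)`` for ``S(TE) = S0*exp(-TE/T2)``.

    The default path is weighted log-linear least squares on positive
    signals (weights proportional to signal squared, which undoes the
    log-transform's noise distortion).  Non-positive signals fall back to a
    nonlinear fit; an all-zero curve is unfittable.  ``refine=True`` runs a
    nonlinear polish after the log-linear estimate.
    """
    signal = np.asarray(signal, dtype=float)
    echoes = np.asarray(echoes, dtype=float)
    if signal.shape != echoes.shape:
        raise InputError("signal and echoes have mismatched lengths")
    echoes = _check_timing(echoes, 2, "echo")
    if not np.all(np.isfinite(signal)):
        raise InputError("signal must be finite")

    failed = T2FitResult(SENTINEL, SENTINEL, SENTINEL, False)
    if np.all(signal == 0):
        return failed

    if np.all(signal > 0):
        w = signal**2
        x, y = echoes, np.log(signal)
        wx = np.sum(w * x) / np.sum(w)
        wy = np.sum(w * y) / np.sum(w)
        denom = np.sum(w * (x - wx) ** 2)
        if denom <= 0:
            return failed
        slope = np.sum(w * (x - wx) * (y - wy)) / denom
        if slope >= 0:  # no decay
            return failed
        t2 = -1.0 / slope
        s0 = math.exp(wy - slope * wx)
        if not refine:
            rmse = float(np.sqrt(np.mean((s0 * np.exp(-echoes / t2) - signal) ** 2)))
            return T2FitResult(float(s0), float(t2), rmse, True)
        x0 = [s0, t2]
    else:
        x0 = [max(signal.max(), 1e-6), max(echoes[-1] - echoes[0], 1.0)]

    try:
        res = least_squares(
            lambda p: p[0] * np.exp(-echoes / p[1]) - signal,
            x0=x0,
            bounds=([0.0, 1e-3], [np.inf, np.inf]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
        )
    except Exception:
        return failed
    if not res.success or not np.all(np.isfinite(res.x)) or res.x[0] <= 0:
        return failed
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return T2FitResult(float(res.x[0]), float(res.x[1]), rmse, True)


def _fit_map(frames, times, mask, pixel_fit, kind) -> ParametricMap:
    n, h, w = frames.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    if not mask.any():
        raise InputError("empty mask: no pixels to fit")
    values = np.full((h, w), SENTINEL)
    quality = np.full((h, w), SENTINEL)
    for r, c in zip(*np.nonzero(mask)):
        fit = pixel_fit(frames[:, r, c], times)
        if fit.converged:
            values[r, c] = fit.T1 if kind == "T1" else fit.T2
            quality[r, c] = fit.rmse
    return ParametricMap(values=values, quality=quality, kind=kind)


def fit_t1_map(series: RecoverySeries) -> ParametricMap:
    """Pixel-by-pixel T1 estimation over the masked pixels of a series."""
    return _fit_map(series.frames, series.delays, series.mask, fit_t1_pixel, "T1")


def fit_t2_map(series: EchoSeries) -> ParametricMap:
    """Pixel-by-pixel T2 estimation over the masked pixels of a series."""
    return _fit_map(series.frames, series.echoes, series.mask, fit_t2_pixel, "T2")


def map_roi_stats(pmap: ParametricMap, roi: np.ndarray) -> dict:
    """Mean, sample SD and count over the valid pixels of an ROI.

    Sentinel (failed/unmasked) pixels are excluded; an ROI with no valid
    pixel is an input error.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.values.shape:
        raise InputError("ROI shape does not match map shape")
    sel = pmap.values[roi & pmap.valid]
    if sel.size == 0:
        raise InputError("ROI contains no valid pixels")
    sd = float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0
    return {"mean": float(np.mean(sel)), "sd": sd, "n": int(sel.size)}
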