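"""Quantitative evaluation of stacks and reconstructions.

Error maps, integrated-intensity curves, PSNR against a clean reference,
ROI decay curves and line profiles, plus the pixel-wise
stretched-exponential decay fit I(t) = I0 exp(-(t/tau)^h) that serves as
the classical comparator for DMD-derived rates (h = 1 recovers a single
exponential; h < 1 indicates kinetic heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

from .stack import ImageStack

#: sentinel PSNR for an identical pair (MSE = 0)
PSNR_INF = float("inf")

#: rss sentinel for a failed / rejected stretched-exponential fit
FIT_FAILED_RSS = float("inf")


def squared_error_map(stack_a: ImageStack, stack_b: ImageStack) -> ImageStack:
    """Per-pixel, per-frame squared difference (a − b)²."""
    if stack_a.data.shape != stack_b.data.shape:
        raise ValueError(
            f"shape mismatch: {stack_a.data.shape} vs {stack_b.data.shape}"
        )
    return ImageStack((stack_a.data - stack_b.data) ** 2, stack_a.dt)


def integrated_intensity(stack: ImageStack) -> np.ndarray:
    """Per-frame sum over all pixels."""
    return stack.data.sum(axis=(1, 2))


def psnr(clean: ImageStack, test: ImageStack) -> float:
    """Peak signal-to-noise ratio 10 log10(peak² / MSE) in dB.

    ``peak`` is the maximum of the clean stack (float stacks carry no
    canonical bit depth). Identical stacks return +inf.
    """
    if clean.data.shape != test.data.shape:
        raise ValueError("shape mismatch between clean and test stacks")
    peak = clean.data.max()
    if peak <= 0:
        raise ValueError("clean stack must contain positive intensities")
    mse = np.mean((clean.data - test.data) ** 2)
    if mse == 0:
        return PSNR_INF
    return float(10.0 * np.log10(peak**2 / mse))


def roi_decay(stack: ImageStack, box: tuple[int, int, int, int]) -> np.ndarray:
    """Mean intensity per frame in a box (row0, col0, height, width)."""
    r0, c0, bh, bw = box
    h, w = stack.image_shape
    if not (0 <= r0 and 0 <= c0 and bh > 0 and bw > 0 and r0 + bh <= h and c0 + bw <= w):
        raise ValueError(f"box {box} outside image bounds {(h, w)}")
    return stack.data[:, r0 : r0 + bh, c0 : c0 + bw].mean(axis=(1, 2))


def line_profile(frame: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
                 n_samples: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity profile along the segment p0→p1 ((x, y) pixels).

    Returns (distance along the line in pixels, sampled intensity).
    """
    h, w = frame.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise ValueError(f"profile endpoint {p} outside image bounds")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    vals = map_coordinates(frame, [ys, xs], order=1, mode="nearest")
    dist = t * float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    return dist, vals


@dataclass
class StretchedExpFit:
    """Result of fitting I(t) = I0 exp(-(t/tau)^h)."""

    I0: float
    tau: float
    h: float
    rss: float
    converged: bool = True

    @property
    def rate(self) -> float:
        """Loss rate constant −1/τ (s⁻¹, Table-style sign convention)."""
        return -1.0 / self.tau

    @property
    def mean_time_constant(self) -> float:
        """Mean relaxation time τ Γ(1/h)/h, correcting for stretching."""
        return self.tau * gamma_fn(1.0 / self.h) / self.h


def stretched_exp_fit(trace: np.ndarray, dt: float) -> StretchedExpFit:
    """Least-squares stretched-exponential fit of a single decay trace.

    Initialization: I0 = first sample; tau = time at which the trace
    first falls to I0/e (linear interpolation, falling back to the trace
    midpoint when it never does); h = 1. Bounds: h in [0.2, 3], tau > 0.
    A trace that does not decay (or a failed optimization) is returned
    flagged with rss = inf.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 samples to fit a stretched exponential")
    if np.any(y <= 0):
        raise ValueError("stretched-exponential fit requires positive intensities")
    t = np.arange(y.size) * dt

    I0_init = y[0]
    target = I0_init / np.e
    below = np.nonzero(y <= target)[0]
    if below.size == 0 or below[0] == 0:
        if y.min() >= 0.99 * I0_init:  # no decay at all
            return StretchedExpFit(I0=I0_init, tau=np.inf, h=1.0,
                                   rss=FIT_FAILED_RSS, converged=False)
        tau_init = t[-1] / 2.0
    else:
        i = below[0]
        frac = (y[i - 1] - target) / (y[i - 1] - y[i])
        tau_init = t[i - 1] + frac * dt

    def resid(p):
        I0, tau, h = p
        return I0 * np.exp(-((t / tau) ** h)) - y

    try:
        sol = least_squares(
            resid,
            x0=[I0_init, max(tau_init, dt), 1.0],
            bounds=([0.0, 1e-12, 0.2], [np.inf, np.inf, 3.0]),
        )
    except Exception:
        return StretchedExpFit(I0=I0_init, tau=max(tau_init, dt), h=1.0,
                               rss=FIT_FAILED_RSS, converged=False)
    if not sol.success:
        return StretchedExpFit(I0=I0_init, tau=max(tau_init, dt), h=1.0,
                               rss=FIT_FAILED_RSS, converged=False)
    I0, tau, h = sol.x
    return StretchedExpFit(I0=float(I0), tau=float(tau), h=float(h),
                           rss=float(np.sum(sol.fun**2)))


def pixelwise_stretched_exp(
    stack: ImageStack,
    mask: np.ndarray | None = None,
    intensity_floor_frac: float = 0.02,
) -> dict[str, np.ndarray]:
    """Per-pixel stretched-exponential fit over a mask.

    Pixels whose initial intensity falls below ``intensity_floor_frac`` of
    the stack maximum at t = 0 are skipped (NaN in the output maps), which
    keeps background pixels out of the statistics.

    Returns maps ``tau``, ``h``, ``rate`` (−1/τ) and a boolean ``fitted``.
    """
    h_img, w_img = stack.image_shape
    if mask is None:
        mask = np.ones((h_img, w_img), dtype=bool)
    floor = intensity_floor_frac * stack.data[0].max()
    tau_map = np.full((h_img, w_img), np.nan)
    h_map = np.full((h_img, w_img), np.nan)
    fitted = np.zeros((h_img, w_img), dtype=bool)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        trace = stack.data[:, r, c]
        if trace[0] < floor or np.any(trace <= 0):
            continue
        res = stretched_exp_fit(trace, stack.dt)
        if res.converged and np.isfinite(res.rss):
            tau_map[r, c] = res.tau
            h_map[r, c] = res.h
            fitted[r, c] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_map = -1.0 / tau_map
    return {"tau": tau_map, "h": h_map, "rate": rate_map, "fitted": fitted}
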