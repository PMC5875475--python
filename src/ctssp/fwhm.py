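"""FWHM estimation for slice sensitivity profiles.

Four estimators: half level from the left side's minimum, from the right
side's, each side independently, and a Gaussian least-squares fit.  Crossings
are located by scanning outward from the peak and linearly interpolating the
first bracketing sample pair on each side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, CrossingRangeError, FitError, InputError, TruncatedProfileError
from .ssp_core import SSPCurve

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548

InterpMode = Literal["left", "right", "two_sided"]


@dataclass
class GaussianFit:
    amplitude: float
    center: float  # mm
    sigma: float  # mm
    baseline: float
    residual_norm: float


@dataclass
class FWHMResult:
    method: str  # left | right | two_sided | gaussian
    fwhm: float  # mm
    left_cross: float  # mm
    right_cross: float  # mm
    half_levels: tuple[float, float]  # (left, right), dimensionless
    fit: Optional[GaussianFit] = None


def _peak_index(v: np.ndarray) -> int:
    ip = int(np.argmax(v))
    if ip == 0 or ip == len(v) - 1:
        raise TruncatedProfileError(
            "profile peak at an endpoint; the scan range did not cover the profile"
        )
    return ip


def _cross_left(z: np.ndarray, v: np.ndarray, ip: int, level: float) -> float:
    """First half-level crossing scanning outward (leftward) from the peak."""
    for i in range(ip - 1, -1, -1):
        if v[i] == level:
            return float(z[i])
        if v[i] < level <= v[i + 1]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    raise CrossingRangeError("no half-maximum crossing on the left side")


def _cross_right(z: np.ndarray, v: np.ndarray, ip: int, level: float) -> float:
    for i in range(ip + 1, len(v)):
        if v[i] == level:
            return float(z[i])
        if v[i] < level <= v[i - 1]:
            frac = (v[i - 1] - level) / (v[i - 1] - v[i])
            return float(z[i - 1] + frac * (z[i] - z[i - 1]))
    raise CrossingRangeError("no half-maximum crossing on the right side")


def fwhm_interp(
    curve: SSPCurve, mode: InterpMode = "two_sided", symmetric: bool = False
) -> FWHMResult:
    """FWHM by linear interpolation at side-derived half levels.

    The half level for side *s* is ``m_s + 0.5·(peak − m_s)`` with ``m_s``
    that side's minimum.  ``left``/``right`` apply that single level to both
    crossings; ``two_sided`` uses each side's own level for its own crossing.
    With ``symmetric=True`` the one-sided modes instead mirror their own
    crossing about the peak sample (alternative reading; see docs).
    """
    if mode not in ("left", "right", "two_sided"):
        raise ConfigError(f"mode must be left|right|two_sided, got {mode!r}")
    z, v = curve.z, curve.v
    if len(v) < 5:
        raise InputError("need at least 5 samples to estimate a FWHM")
    ip = _peak_index(v)
    peak = v[ip]
    h_left = v[: ip + 1].min() + 0.5 * (peak - v[: ip + 1].min())
    h_right = v[ip:].min() + 0.5 * (peak - v[ip:].min())
    if mode == "left":
        level_l = level_r = h_left
    elif mode == "right":
        level_l = level_r = h_right
    else:
        level_l, level_r = h_left, h_right

    if symmetric and mode in ("left", "right"):
        if mode == "left":
            lc = _cross_left(z, v, ip, level_l)
            rc = 2 * z[ip] - lc
        else:
            rc = _cross_right(z, v, ip, level_r)
            lc = 2 * z[ip] - rc
    else:
        lc = _cross_left(z, v, ip, level_l)
        rc = _cross_right(z, v, ip, level_r)
    width = rc - lc
    if not width > 0:
        raise CrossingRangeError("non-positive FWHM from crossings")
    return FWHMResult(
        method=mode, fwhm=width, left_cross=lc, right_cross=rc,
        half_levels=(level_l, level_r),
    )


def fwhm_gauss(curve: SSPCurve, fit_baseline: bool = True) -> FWHMResult:
    """FWHM from a least-squares Gaussian fit ``A·exp(−(z−μ)²/(2σ²)) + b``.

    The baseline ``b`` is fitted by default but constrained to |b| ≤ 0.2
    (curves arrive background-corrected); disable with ``fit_baseline=False``.
    """
    z, v = curve.z, curve.v
    if len(v) < 5:
        raise InputError("need at least 5 samples to fit a Gaussian")
    ip = _peak_index(v)
    interval = float(np.median(np.diff(z)))
    span = float(z[-1] - z[0])
    try:
        sigma0 = fwhm_interp(curve, "two_sided").fwhm / GAUSSIAN_FWHM_FACTOR
    except (CrossingRangeError, InputError):
        sigma0 = span / 4.0
    p0 = [float(v[ip]), float(z[ip]), sigma0]
    lower = [1e-9, z[0], interval / 100.0]
    upper = [10.0 * max(v[ip], 1e-9), z[-1], 2.0 * span]
    if fit_baseline:
        p0.append(0.0)
        lower.append(-0.2)
        upper.append(0.2)

        def model(x, a, mu, sigma, b):
            return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + b

    else:

        def model(x, a, mu, sigma):
            return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            model, z, v, p0=p0, bounds=(lower, upper),
            xtol=1e-8, ftol=1e-8, maxfev=500,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, sigma = popt[:3]
    b = popt[3] if fit_baseline else 0.0
    if sigma < interval / 2.0:
        warnings.warn(
            f"fitted sigma {sigma:.4g} mm is below half the sampling interval "
            f"({interval:.4g} mm); the profile is under-resolved",
            stacklevel=2,
        )
    residual = float(np.linalg.norm(model(z, *popt) - v))
    width = GAUSSIAN_FWHM_FACTOR * float(sigma)
    return FWHMResult(
        method="gaussian",
        fwhm=width,
        left_cross=float(mu) - width / 2.0,
        right_cross=float(mu) + width / 2.0,
        half_levels=(0.5, 0.5),
        fit=GaussianFit(
            amplitude=float(a), center=float(mu), sigma=float(sigma),
            baseline=float(b), residual_norm=residual,
        ),
    )


def estimate(curve: SSPCurve, method: str) -> FWHMResult:
    """Dispatch: method in {left, right, two_sided, gaussian}."""
    if method == "gaussian":
        return fwhm_gauss(curve)
    return fwhm_interp(curve, method)  # type: ignore[arg-type]
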