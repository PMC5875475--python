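"""Build background-corrected, normalized slice sensitivity profiles.

An ROI is fixed in pixel coordinates and propagated through every slice; the
per-slice mean or maximum HU is background-corrected using the average of the
two outermost slices, then normalized to unit peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .dicom_io import ImageSeries
from .errors import BoundsError, ConfigError, DegenerateSignalError, InputError

Statistic = Literal["mean", "max"]


@dataclass
class ROISpec:
    """Region of interest fixed in pixel coordinates across all slices.

    Circles include every pixel whose center lies within ``radius`` of
    ``center`` (inclusive); rectangles are ``size = (height, width)`` pixel
    blocks centered on ``center``.
    """

    shape: Literal["circle", "rectangle"]
    center: tuple[float, float]  # (row, col) pixels
    radius: float | None = None
    size: tuple[int, int] | None = None  # (height, width) pixels
    placement: Literal["manual", "auto"] = "manual"

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.radius is None or self.radius < 0:
                raise ConfigError("circle ROI requires a non-negative radius")
        elif self.shape == "rectangle":
            if self.size is None or self.size[0] < 1 or self.size[1] < 1:
                raise ConfigError("rectangle ROI requires size >= (1, 1)")
        else:
            raise ConfigError(f"unknown ROI shape: {self.shape}")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask; raises if the ROI leaves the image."""
        rows, cols = image_shape
        if self.shape == "circle":
            r0, c0 = self.center
            rr, cc = np.ogrid[:rows, :cols]
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2
            lo_r, hi_r = r0 - self.radius, r0 + self.radius
            lo_c, hi_c = c0 - self.radius, c0 + self.radius
        else:
            h, w = self.size
            top = int(round(self.center[0] - (h - 1) / 2))
            left = int(round(self.center[1] - (w - 1) / 2))
            lo_r, hi_r, lo_c, hi_c = top, top + h - 1, left, left + w - 1
            mask = np.zeros((rows, cols), dtype=bool)
            mask[max(top, 0) : top + h, max(left, 0) : left + w] = True
        if lo_r < 0 or lo_c < 0 or hi_r > rows - 1 or hi_c > cols - 1:
            raise BoundsError(f"ROI extends outside the {rows}x{cols} image")
        if not mask.any():
            raise BoundsError("ROI contains no pixels")
        return mask


#: Stand-in presets for the four evaluated ROI geometries (sizes chosen, not
#: prescribed): small circle, large circle, small square, offset rectangle.
ROI_PRESETS = {
    "roi1": {"shape": "circle", "radius": 3.0, "offset": (0, 0)},
    "roi2": {"shape": "circle", "radius": 10.0, "offset": (0, 0)},
    "roi3": {"shape": "rectangle", "size": (5, 5), "offset": (0, 0)},
    "roi4": {"shape": "rectangle", "size": (9, 5), "offset": (0, 3)},
}


def make_preset_roi(name: str, center: tuple[float, float]) -> ROISpec:
    """Instantiate a named preset centered (plus any preset offset) at *center*."""
    if name not in ROI_PRESETS:
        raise ConfigError(f"unknown ROI preset {name!r}; choose from {sorted(ROI_PRESETS)}")
    p = ROI_PRESETS[name]
    c = (center[0] + p["offset"][0], center[1] + p["offset"][1])
    return ROISpec(
        shape=p["shape"], center=c, radius=p.get("radius"), size=p.get("size"),
    )


@dataclass
class SSPCurve:
    """Slice sensitivity profile: normalized response vs axial position."""

    z: np.ndarray  # positions, mm
    v: np.ndarray  # dimensionless values, peak == 1
    statistic: Statistic
    background: float  # HU subtracted before normalization
    norm_factor: float  # HU divided out

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.z) != len(self.v):
            raise InputError("z and v must have equal length")
        if not np.all(np.diff(self.z) > 0):
            raise InputError("z must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_mm": self.z, "value": self.v})


def sample_roi(series: ImageSeries, roi: ROISpec, statistic: Statistic = "max") -> np.ndarray:
    """Per-slice mean or max HU over the (fixed) ROI."""
    if statistic not in ("mean", "max"):
        raise ConfigError(f"statistic must be 'mean' or 'max', got {statistic!r}")
    mask = roi.mask(series.slices[0].pixels.shape)
    reduce = np.mean if statistic == "mean" else np.max
    return np.array([reduce(sl.pixels[mask]) for sl in series.slices], dtype=float)


def background_correct(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the average of the two outermost samples from every element.

    Returns ``(corrected, background)``.  Warns when either outermost value
    exceeds 10% of the peak — the scan range likely missed the profile tails.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise InputError("background correction needs at least 3 samples")
    peak = values.max()
    if peak > 0 and max(abs(values[0]), abs(values[-1])) > 0.1 * peak:
        warnings.warn(
            "outermost samples exceed 10% of the peak; the scan range may not "
            "cover the profile tails",
            stacklevel=2,
        )
    background = (values[0] + values[-1]) / 2.0
    return values - background, float(background)


def normalize(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide by the maximum element; returns ``(normalized, norm_factor)``."""
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if not peak > 0:
        raise DegenerateSignalError(f"non-positive maximum ({peak:g}); no usable signal")
    return values / peak, float(peak)


def build_ssp(series: ImageSeries, roi: ROISpec, statistic: Statistic = "max") -> SSPCurve:
    """sample_roi → background_correct → normalize, paired with slice positions."""
    raw = sample_roi(series, roi, statistic)
    corrected, background = background_correct(raw)
    normed, factor = normalize(corrected)
    return SSPCurve(
        z=series.positions,
        v=normed,
        statistic=statistic,
        background=background,
        norm_factor=factor,
    )


def auto_place_roi(
    series: ImageSeries,
    shape: Literal["circle", "rectangle"] = "circle",
    size: float = 3.0,
) -> ROISpec:
    """Center an ROI on the hottest pixel across the whole stack.

    Falls back to the image center (with a warning) when the series is blank;
    ties beyond 1e-9 relative tolerance pick the first maximum in scan order.
    """
    stack = np.stack([sl.pixels for sl in series.slices])
    vmax, vmin = stack.max(), stack.min()
    rows, cols = stack.shape[1:]
    if vmax == vmin:
        warnings.warn("blank series: no maximum to lock onto; using image center", stacklevel=2)
        center = ((rows - 1) / 2, (cols - 1) / 2)
    else:
        hits = np.argwhere(stack >= vmax - 1e-9 * max(abs(vmax), 1.0))
        if len(hits) > 1 and not (len(np.unique(hits[:, 1])) == 1 and len(np.unique(hits[:, 2])) == 1):
            warnings.warn(
                f"{len(hits)} tied maxima; using the first in scan order", stacklevel=2
            )
        center = (float(hits[0][1]), float(hits[0][2]))
    # clamp so the ROI stays inside the image
    margin = size if shape == "circle" else (size - 1) / 2
    center = (
        min(max(center[0], margin), rows - 1 - margin),
        min(max(center[1], margin), cols - 1 - margin),
    )
    if shape == "circle":
        return ROISpec(shape="circle", center=center, radius=size, placement="auto")
    s = int(size)
    return ROISpec(shape="rectangle", center=center, size=(s, s), placement="auto")
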