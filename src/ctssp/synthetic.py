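"""Synthetic point-response phantom series with known ground-truth profile.

Models the reconstructed image stack directly: each slice is a 2-D Gaussian
blob whose amplitude follows a chosen axial weight function (Gaussian by
default) of the slice's offset from the object, plus background and optional
additive HU noise.  The axial grid spans ±(range_multiplier × thickness) at
an interval of thickness / interval_divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .dicom_io import ImageSeries, SliceImage
from .errors import ConfigError
from .fwhm import GAUSSIAN_FWHM_FACTOR

#: inert acquisition tags carried through to the series metadata
DEFAULT_ACQUISITION_META = {"kvp": "120", "mas": "325", "pitch": "0.969", "sfov": "Head"}

_REQUIRED_FIELDS = ("true_fwhm", "thickness")


@dataclass
class SimConfig:
    """Ground-truth profile shape plus acquisition grid for the simulator."""

    true_fwhm: float  # ground-truth axial FWHM, mm
    thickness: float  # nominal slice thickness T, mm
    profile: Literal["gaussian", "triangular"] = "gaussian"
    interval_divisor: float = 10.0  # k: slices at Δz = T/k
    range_multiplier: float = 5.0  # m: grid spans ±m·T
    object_z: float = 0.0  # mm
    object_xy: Optional[tuple[float, float]] = None  # (row, col) px; default center
    peak_hu: float = 1000.0
    background_hu: float = 0.0
    inplane_sigma0: float = 0.4  # mm
    inplane_spread_coeff: float = 0.0  # c: σ_xy = σ0·(1 + c·|Δz|/true_fwhm)
    noise_sd: float = 0.0  # HU
    image_size: int = 64  # pixels (square)
    pixel_spacing: float = 0.5  # mm
    seed: int = 0
    acquisition_meta: dict = field(default_factory=lambda: dict(DEFAULT_ACQUISITION_META))

    def __post_init__(self) -> None:
        for name in (
            "true_fwhm", "thickness", "interval_divisor", "range_multiplier",
            "peak_hu", "inplane_sigma0", "pixel_spacing",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.inplane_spread_coeff < 0 or self.noise_sd < 0:
            raise ConfigError("inplane_spread_coeff and noise_sd must be >= 0")
        if self.profile not in ("gaussian", "triangular"):
            raise ConfigError(f"profile must be gaussian|triangular, got {self.profile!r}")
        if self.image_size < 1:
            raise ConfigError("image_size must be >= 1")
        if self.object_xy is not None:
            r, c = self.object_xy
            if not (0 <= r <= self.image_size - 1 and 0 <= c <= self.image_size - 1):
                raise ConfigError(f"object_xy {self.object_xy} outside {self.image_size}px image")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        for name in _REQUIRED_FIELDS:
            if name not in data:
                raise ConfigError(f"missing required field: {name}")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown field(s): {sorted(unknown)}")
        if "object_xy" in data and data["object_xy"] is not None:
            data = {**data, "object_xy": tuple(data["object_xy"])}
        return cls(**data)


def n_slice_positions(m: float, k: float) -> int:
    """Grid positions over ±m·T at Δz = T/k: 2·m·k + 1, rounded up."""
    if not (m > 0 and k > 0):
        raise ConfigError("range multiplier and interval divisor must be > 0")
    return math.ceil(2.0 * m * k - 1e-9) + 1


def slice_grid(config: SimConfig) -> np.ndarray:
    """Axial positions, mm, spanning ±range_multiplier·thickness."""
    half = config.range_multiplier * config.thickness
    n = n_slice_positions(config.range_multiplier, config.interval_divisor)
    return np.linspace(-half, half, n)


def axial_weight(dz, config: SimConfig):
    """Unit-peak axial response at offset *dz* mm from the object plane."""
    dz = np.asarray(dz, dtype=float)
    if config.profile == "gaussian":
        sigma_z = config.true_fwhm / GAUSSIAN_FWHM_FACTOR
        w = np.exp(-(dz**2) / (2.0 * sigma_z**2))
    else:
        w = np.maximum(0.0, 1.0 - np.abs(dz) / config.true_fwhm)
    return w if w.ndim else float(w)


def generate_series(config: SimConfig) -> ImageSeries:
    """Simulate the reconstructed overlapping-slice stack of a point object.

    Slice at position z gets
    ``background + peak·axial_weight(z−object_z)·G2D(σ_xy(z−object_z)) + noise``
    with the in-plane Gaussian spread growing as σ0·(1 + c·|Δz|/true_fwhm).
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    z_grid = slice_grid(config)
    interval = float(z_grid[1] - z_grid[0])
    n_px = config.image_size
    r0, c0 = config.object_xy if config.object_xy is not None else (n_px // 2, n_px // 2)
    rr, cc = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    # squared in-plane distance from the object, mm²
    d2 = ((rr - r0) * config.pixel_spacing) ** 2 + ((cc - c0) * config.pixel_spacing) ** 2

    slices = []
    for z in z_grid:
        dz = z - config.object_z
        w = axial_weight(dz, config)
        sigma_xy = config.inplane_sigma0 * (
            1.0 + config.inplane_spread_coeff * abs(dz) / config.true_fwhm
        )
        blob = np.exp(-d2 / (2.0 * sigma_xy**2))
        pixels = config.background_hu + config.peak_hu * w * blob
        if config.noise_sd > 0:
            pixels = pixels + rng.normal(0.0, config.noise_sd, size=pixels.shape)
        slices.append(
            SliceImage(
                pixels=pixels,
                z=float(z),
                thickness=config.thickness,
                pixel_spacing=(config.pixel_spacing, config.pixel_spacing),
            )
        )
    return ImageSeries(
        slices=slices,
        interval=interval,
        acquisition_meta=dict(config.acquisition_meta),
        spacing_tol=max(1e-6, 1e-12 * abs(z_grid[-1])),
    )


def ground_truth(config: SimConfig) -> dict:
    """JSON-serializable sidecar describing the simulated series."""
    z_grid = slice_grid(config)
    return {
        "true_fwhm_mm": config.true_fwhm,
        "profile": config.profile,
        "thickness_mm": config.thickness,
        "interval_mm": float(z_grid[1] - z_grid[0]),
        "n_slices": len(z_grid),
        "z_first_mm": float(z_grid[0]),
        "z_last_mm": float(z_grid[-1]),
        "object_z_mm": config.object_z,
        "seed": config.seed,
    }
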