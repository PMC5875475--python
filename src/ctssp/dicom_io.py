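"""Read and write overlapping-slice CT series with HU scaling and axial ordering.

The axial coordinate is signed millimetres, superior positive; series are
always sorted ascending in z.  Reading prefers the z component of Image
Position (Patient) and falls back to the Slice Location tag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dicom
from .errors import AmbiguityError, InputError, SpacingError

logger = logging.getLogger(__name__)

#: acquisition_meta keys serialized into the series-description tag
_META_KEYS = ("kvp", "mas", "pitch", "sfov")


@dataclass
class SliceImage:
    """One reconstructed slice: HU pixels at a signed axial position."""

    pixels: np.ndarray  # 2-D float array of HU values
    z: float  # axial position, mm (superior positive)
    thickness: float  # nominal slice thickness T, mm
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (row, col) mm

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("pixels must be a non-empty 2-D array")
        if not self.thickness > 0:
            raise InputError("thickness must be > 0")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise InputError("pixel_spacing must be > 0")


@dataclass
class ImageSeries:
    """Ordered stack of slices on a uniform axial grid."""

    slices: list[SliceImage]
    interval: float  # Δz between consecutive slices, mm
    acquisition_meta: dict = field(default_factory=dict)
    #: allowed |Δz − interval| deviation, mm (readers widen this to 1% of Δz)
    spacing_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.slices) < 3:
            raise InputError("a series needs at least 3 slices")
        z = self.positions
        dz = np.diff(z)
        if not np.all(dz > 0):
            raise InputError("slice positions must be strictly increasing (no duplicates)")
        if np.any(np.abs(dz - self.interval) > self.spacing_tol):
            raise SpacingError(
                f"non-uniform spacing: max deviation {np.max(np.abs(dz - self.interval)):.3g} mm "
                f"exceeds tolerance {self.spacing_tol:.3g} mm"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)

    @property
    def thickness(self) -> float:
        return self.slices[0].thickness

    def __len__(self) -> int:
        return len(self.slices)


def read_series(path) -> ImageSeries:
    """Read a directory of single-frame CT DICOM files into an :class:`ImageSeries`.

    Pixel values are converted to HU via the rescale slope/intercept tags;
    slices are sorted by axial position regardless of filename order.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append((f, _dicom.read_file(f)))
        except InputError:
            logger.debug("skipping non-DICOM file %s", f)
    if not datasets:
        raise InputError(f"no readable DICOM files in {directory}")
    if len(datasets) < 3:
        raise InputError(f"need at least 3 slices, found {len(datasets)}")

    uids = {ds.get_str(_dicom.TAG_SERIES_UID, "") for _, ds in datasets}
    if len(uids) > 1:
        raise AmbiguityError(f"directory mixes {len(uids)} series UIDs")

    position_source = None
    slices = []
    for f, ds in datasets:
        ipp = ds.get_floats(_dicom.TAG_IMAGE_POSITION)
        if ipp is not None and len(ipp) == 3:
            z = ipp[2]
            position_source = position_source or "image position (patient)"
        else:
            z = ds.get_float(_dicom.TAG_SLICE_LOCATION)
            if z is None:
                raise InputError(f"{f}: no image position or slice location tag")
            position_source = position_source or "slice location"
        slope = ds.get_float(_dicom.TAG_RESCALE_SLOPE)
        intercept = ds.get_float(_dicom.TAG_RESCALE_INTERCEPT)
        if slope is None or intercept is None:
            warnings.warn(
                f"{f}: missing rescale tags, assuming slope 1 / intercept 0",
                stacklevel=2,
            )
            slope = 1.0 if slope is None else slope
            intercept = 0.0 if intercept is None else intercept
        spacing = ds.get_floats(_dicom.TAG_PIXEL_SPACING, [1.0, 1.0])
        hu = slope * ds.pixel_array().astype(float) + intercept
        slices.append(
            SliceImage(
                pixels=hu,
                z=z,
                thickness=ds.get_float(_dicom.TAG_SLICE_THICKNESS, 1.0),
                pixel_spacing=(spacing[0], spacing[1]),
            )
        )
    logger.info("read %d slices, positions from %s", len(slices), position_source)

    slices.sort(key=lambda s: s.z)
    dz = np.diff([s.z for s in slices])
    if np.any(dz <= 0):
        raise InputError("duplicate slice positions in series")
    interval = float(np.median(dz))
    if np.any(np.abs(dz - interval) > 0.01 * interval):
        raise SpacingError(
            f"slice spacing deviates more than 1% from the nominal interval {interval:.4g} mm"
        )
    meta = _meta_from_description(datasets[0][1].get_str(_dicom.TAG_SERIES_DESCRIPTION, ""))
    return ImageSeries(
        slices=slices,
        interval=interval,
        acquisition_meta=meta,
        spacing_tol=max(1e-6, 0.01 * interval),
    )


def write_series(
    series: ImageSeries,
    path,
    *,
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str | None = None,
) -> list[Path]:
    """Write a series as one DICOM file per slice; returns the paths written.

    HU values are quantized to integer stored values via
    ``stored = round((HU − intercept)/slope)``, so a round-trip reproduces HU
    to within half a stored-value quantum.
    """
    series.validate()
    directory = Path(path)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {directory}: {exc}") from exc
    uid = series_uid or _dicom.new_uid()
    description = ";".join(
        f"{k}={series.acquisition_meta[k]}" for k in _META_KEYS if k in series.acquisition_meta
    )
    paths = []
    for i, sl in enumerate(series.slices):
        stored = np.rint((sl.pixels - intercept) / slope)
        if stored.min() < -32768 or stored.max() > 32767:
            warnings.warn("HU values clipped to the int16 stored range", stacklevel=2)
            stored = np.clip(stored, -32768, 32767)
        out = directory / f"slice_{i + 1:04d}.dcm"
        _dicom.write_ct_slice(
            out,
            stored.astype(np.int16),
            z=sl.z,
            thickness=sl.thickness,
            pixel_spacing=sl.pixel_spacing,
            slope=slope,
            intercept=intercept,
            series_uid=uid,
            sop_uid=f"{uid}.{i + 1}",
            instance_number=i + 1,
            series_description=description,
        )
        paths.append(out)
    return paths


def _meta_from_description(description: str) -> dict:
    meta = {}
    for part in description.split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            meta[key] = value
    return meta
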