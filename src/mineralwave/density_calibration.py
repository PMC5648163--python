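"""Grey-value to hydroxyapatite-density calibration for enamel sections.

Synchrotron virtual sections store enamel as grayscale images whose pixel
values are linear in hydroxyapatite (HAp) density.  Each scan batch has its
own calibration line ``rho = slope * Px + intercept`` (g/cm^3); this module
holds the batch constants, applies them to whole sections, and loads the
section images plus their tabular metadata sidecar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

logger = logging.getLogger("mineralwave")

#: Reference maximum HAp density (g/cm^3), the densest mature mid-enamel value
#: measured in the source ontogenetic series; maturation landmarks and the
#: percent scale of the assembled model are expressed relative to it.
REFERENCE_MAX_DENSITY = 2.62

#: Per-batch linear calibration constants (slope g/cm^3 per grey unit,
#: intercept g/cm^3) for the two synchrotron scan batches.
BATCH_CALIBRATIONS = {
    1: (6.9e-5, 1.54),
    2: (2.8e-4, 1.49),
}


class CalibrationError(ValueError):
    """Raised for invalid calibration parameters or batch mismatches."""


@dataclass(frozen=True)
class CalibrationParams:
    """A linear grey->density calibration for one scan batch.

    Attributes
    ----------
    slope : float
        Density increment per grey unit (g/cm^3 per grey value). Must be > 0.
    intercept : float
        Density at grey value 0 (g/cm^3).
    batch_id : int
        Scan batch the calibration belongs to (1 or 2 for the real data;
        synthetic batches may use other ids).
    """

    slope: float
    intercept: float
    batch_id: int = 1

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")

    @classmethod
    def for_batch(cls, batch_id: int) -> "CalibrationParams":
        """Return the default calibration line for a scan batch."""
        try:
            slope, intercept = BATCH_CALIBRATIONS[batch_id]
        except KeyError:
            raise CalibrationError(
                f"no default calibration for batch {batch_id!r}; known: "
                f"{sorted(BATCH_CALIBRATIONS)}"
            ) from None
        return cls(slope=slope, intercept=intercept, batch_id=batch_id)

    def density_range(self, grey_max: float = 65535.0) -> tuple[float, float]:
        """Representable density interval for a given grey dynamic range."""
        return (self.intercept, self.intercept + self.slope * grey_max)


@dataclass
class ToothSection:
    """One specimen's raw grayscale virtual enamel section plus metadata."""

    specimen_id: str
    age_days: float
    batch: int
    molar: str  # "M1" or "M2"
    worn: bool
    pixels: np.ndarray  # 2D grey values, >= 0; 0 is background
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("section pixels must be a 2D grid")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")


@dataclass
class DensityMap:
    """Calibrated densities (g/cm^3) with a formed-enamel mask."""

    densities: np.ndarray  # 2D, g/cm^3; meaningful only where mask is True
    mask: np.ndarray  # 2D bool, True = formed enamel
    pixel_size_mm: float
    specimen_id: str = ""
    age_days: float = np.nan

    def crop(self, rows: slice, cols: slice) -> "DensityMap":
        return DensityMap(
            densities=self.densities[rows, cols],
            mask=self.mask[rows, cols],
            pixel_size_mm=self.pixel_size_mm,
            specimen_id=self.specimen_id,
            age_days=self.age_days,
        )


def grey_to_density(px, calib: CalibrationParams):
    """Convert pixel grey value(s) to HAp density (g/cm^3).

    Applies the batch calibration line ``rho = slope * px + intercept``.
    Accepts scalars or arrays; negative grey values are a domain error.
    """
    px = np.asarray(px, dtype=float)
    if np.any(px < 0):
        raise ValueError("grey values must be >= 0")
    out = calib.slope * px + calib.intercept
    return float(out) if out.ndim == 0 else out


def density_to_grey(rho, calib: CalibrationParams):
    """Invert the calibration line: grey = (rho - intercept) / slope."""
    rho = np.asarray(rho, dtype=float)
    out = (rho - calib.intercept) / calib.slope
    return float(out) if out.ndim == 0 else out


def calibrate_section(
    section: ToothSection,
    calib: CalibrationParams,
    background_threshold: float = 0.0,
) -> DensityMap:
    """Convert a section's grey values to a density map.

    Grey values at or below ``background_threshold`` are background (the
    generator reserves grey 0 for unformed regions; real sections with a
    nonzero floor can raise the threshold).  The calibration batch must match
    the section's batch.
    """
    if calib.batch_id != section.batch:
        raise CalibrationError(
            f"calibration batch {calib.batch_id} does not match section batch "
            f"{section.batch} (specimen {section.specimen_id})"
        )
    mask = section.pixels > background_threshold
    densities = np.zeros(section.pixels.shape, dtype=float)
    if mask.any():
        densities[mask] = grey_to_density(section.pixels[mask], calib)
    return DensityMap(
        densities=densities,
        mask=mask,
        pixel_size_mm=section.pixel_size_mm,
        specimen_id=section.specimen_id,
        age_days=section.age_days,
    )


MANIFEST_COLUMNS = ["id", "age_days", "batch", "molar", "worn", "filename"]


def _read_grey_image(path: Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as a float array, promoting 8-bit inputs."""
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with filename context
        raise IOError(f"could not read section image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        warnings.warn(
            f"{path.name}: 8-bit image promoted to 16-bit grey range", stacklevel=2
        )
        arr = arr.astype(np.uint16) * 257  # 255 -> 65535
    return arr.astype(float)


def load_manifest(
    manifest_path, image_dir=None, pixel_size_mm: float = 0.046
) -> list[ToothSection]:
    """Load sections listed in a CSV manifest.

    The manifest has columns ``id, age_days, batch, molar, worn, filename``
    (death-day first, then scan batch, then ID).
    Rows whose image file is missing are reported and skipped; unreadable
    images raise an I/O error naming the file.  Negative ages are accepted:
    first molars initiate prenatally.
    """
    manifest_path = Path(manifest_path)
    image_dir = Path(image_dir) if image_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    sections: list[ToothSection] = []
    for row in df.itertuples(index=False):
        img_path = image_dir / str(row.filename)
        if not img_path.exists():
            logger.warning("manifest row %s: image %s missing, skipped", row.id, img_path)
            continue
        pixels = _read_grey_image(img_path)
        sections.append(
            ToothSection(
                specimen_id=str(row.id),
                age_days=float(row.age_days),
                batch=int(row.batch),
                molar=str(row.molar),
                worn=bool(row.worn),
                pixels=pixels,
                pixel_size_mm=pixel_size_mm,
            )
        )
    return sections


def save_density_maps(maps: list[DensityMap], path) -> None:
    """Cache density maps as an HDF5 file, one group per specimen."""
    import h5py

    with h5py.File(path, "w") as f:
        for dmap in maps:
            g = f.create_group(dmap.specimen_id)
            g.create_dataset("densities", data=dmap.densities)
            g.create_dataset("mask", data=dmap.mask)
            g.attrs["pixel_size_mm"] = dmap.pixel_size_mm
            g.attrs["age_days"] = dmap.age_days


def load_density_maps(path) -> list[DensityMap]:
    """Load density maps cached by :func:`save_density_maps`."""
    import h5py

    maps = []
    with h5py.File(path, "r") as f:
        for sid in f:
            g = f[sid]
            maps.append(
                DensityMap(
                    densities=g["densities"][()],
                    mask=g["mask"][()].astype(bool),
                    pixel_size_mm=float(g.attrs["pixel_size_mm"]),
                    specimen_id=sid,
                    age_days=float(g.attrs["age_days"]),
                )
            )
    maps.sort(key=lambda m: m.age_days)
    return maps
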