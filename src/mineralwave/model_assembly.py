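"""Assembly of per-pixel posteriors into a portable four-dataset HDF5 schema,
and derived products: daily interpolation, mineralization-rate fields,
time-averaging maps, and animation frame export.

The assembled model holds exactly four datasets, in the model's distribution format:

``age_mask``
    pixels (rows) x specimens (columns), binary: 1 where the pixel exists
    in that specimen's section.
``ages``
    the size-modeled age (days) of each specimen.
``locations``
    pixels x 2 standardized tooth coordinates (EDJ distance mm, relative
    depth).
``pct_min_samples``
    specimen-ages (pages) x pixels (rows) x retained samples (columns),
    densities stored as percent of the reference maximum; -1 marks
    pixel-ages where the pixel does not exist (age_mask 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .density_calibration import REFERENCE_MAX_DENSITY
from .mineralization_mcmc import PixelSeries, TrajectoryPosterior

logger = logging.getLogger("mineralwave")

ABSENT_SENTINEL = -1.0


class AssemblyError(ValueError):
    """Raised when per-pixel posteriors cannot be assembled consistently."""


@dataclass
class MineralizationModel:
    """In-memory view of the four-dataset mineralization model."""

    age_mask: np.ndarray  # (n_pixels, n_specimens) uint8
    ages: np.ndarray  # (n_specimens,) days
    locations: np.ndarray  # (n_pixels, 2)
    pct_min_samples: np.ndarray  # (n_specimens, n_pixels, n_samples), percent
    reference_density: float = REFERENCE_MAX_DENSITY
    edj_bin_mm: float = np.nan
    n_depth_bins: int = 0

    @property
    def n_pixels(self) -> int:
        return self.locations.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pct_min_samples.shape[2]

    def trajectories(self, pixel: int) -> tuple[np.ndarray, np.ndarray]:
        """(present ages, samples in g/cm^3 of shape (n_keep, n_present))."""
        present = self.age_mask[pixel].astype(bool)
        pct = self.pct_min_samples[present, pixel, :].T  # (n_keep, n_present)
        return self.ages[present], pct / 100.0 * self.reference_density

    def daily_estimate_count(self, n_days: int = 280) -> int:
        """Number of density estimates a daily interpolation would contain,
        from shape metadata alone (nothing is materialized)."""
        return int(self.n_pixels) * int(n_days) * int(self.n_samples)


def planned_estimate_count(n_pixels: int, n_days: int, n_keep: int) -> int:
    """Density estimates in a daily-interpolated model of the given shape."""
    return int(n_pixels) * int(n_days) * int(n_keep)


def assemble_model(
    posteriors: list[TrajectoryPosterior],
    series_list: list[PixelSeries],
    output_path=None,
    reference_density: float = REFERENCE_MAX_DENSITY,
    edj_bin_mm: float = np.nan,
    n_depth_bins: int = 0,
    seed: int = 0,
) -> MineralizationModel:
    """Assemble per-pixel posteriors into the four-dataset model.

    All pixels must share one specimen roster (the same time grid).  If
    ``output_path`` is given the model is also written to HDF5 with the
    exact dataset names and axis conventions of the distribution schema, plus
    file attributes recording the reference density, sentinel and seed.
    """
    if len(posteriors) != len(series_list) or not posteriors:
        raise AssemblyError("need matching, non-empty posterior and series lists")
    times = series_list[0].times
    for s in series_list[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise AssemblyError("specimen roster differs across pixels")
    n_keep = {p.samples.shape[0] for p in posteriors}
    if len(n_keep) != 1:
        raise AssemblyError(f"inconsistent retained-sample counts: {sorted(n_keep)}")
    n_keep = n_keep.pop()

    n_pix, n_spec = len(posteriors), times.size
    age_mask = np.zeros((n_pix, n_spec), np.uint8)
    locations = np.zeros((n_pix, 2))
    pct = np.full((n_spec, n_pix, n_keep), ABSENT_SENTINEL)
    for i, (post, series) in enumerate(zip(posteriors, series_list)):
        present = series.present
        age_mask[i] = present
        locations[i] = post.location
        pct[present, i, :] = (post.samples / reference_density * 100.0).T
    model = MineralizationModel(
        age_mask=age_mask,
        ages=times.copy(),
        locations=locations,
        pct_min_samples=pct,
        reference_density=reference_density,
        edj_bin_mm=edj_bin_mm,
        n_depth_bins=n_depth_bins,
    )
    if output_path is not None:
        write_model(model, output_path, seed=seed)
    return model


def write_model(model: MineralizationModel, path, seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("age_mask", data=model.age_mask)
        f.create_dataset("ages", data=model.ages)
        f.create_dataset("locations", data=model.locations)
        f.create_dataset("pct_min_samples", data=model.pct_min_samples)
        f.attrs["reference_density_g_cm3"] = model.reference_density
        f.attrs["absent_sentinel"] = ABSENT_SENTINEL
        f.attrs["seed"] = seed
        f.attrs["edj_bin_mm"] = model.edj_bin_mm
        f.attrs["n_depth_bins"] = model.n_depth_bins
        f.attrs["axis_convention"] = (
            "age_mask: pixels x specimens; pct_min_samples: specimen-ages x "
            "pixels x samples (percent of reference maximum; -1 = absent)"
        )


def read_model(path) -> MineralizationModel:
    with h5py.File(path, "r") as f:
        return MineralizationModel(
            age_mask=f["age_mask"][()],
            ages=f["ages"][()],
            locations=f["locations"][()],
            pct_min_samples=f["pct_min_samples"][()],
            reference_density=float(f.attrs.get("reference_density_g_cm3", REFERENCE_MAX_DENSITY)),
            edj_bin_mm=float(f.attrs.get("edj_bin_mm", np.nan)),
            n_depth_bins=int(f.attrs.get("n_depth_bins", 0)),
        )


# ---------------------------------------------------------------------------
# Derived products
# ---------------------------------------------------------------------------

@dataclass
class DailyTrajectories:
    """Posterior trajectories interpolated onto a uniform daily grid."""

    days: np.ndarray  # (n_days,)
    values: np.ndarray  # (n_pixels, n_days) summary, or (n_keep, n_pixels, n_days)
    locations: np.ndarray
    pixel_index: np.ndarray  # indices into the model's pixel axis
    reference_density: float


def interpolate_daily(
    model: MineralizationModel,
    n_days: int = 280,
    t_start: float | None = None,
    statistic: str | None = "mean",
) -> DailyTrajectories:
    """Linearly interpolate retained trajectories onto a daily grid.

    The window spans ``[t_start, t_start + n_days)`` days; by default it is
    anchored at the earliest age any pixel is present (for real-data runs,
    pass the fitted initiation day).  Days before a pixel's first presence
    are 0 (unformed); days beyond its last presence hold the final value.
    Linear interpolation preserves monotonicity.  ``statistic`` may be
    "mean", "median" (per-day summary across retained samples) or None to
    keep every sample.  Pixels present in fewer than 2 specimens are
    excluded and logged.
    """
    mask = model.age_mask.astype(bool)
    usable = np.flatnonzero(mask.sum(axis=1) >= 2)
    n_drop = model.n_pixels - usable.size
    if n_drop:
        logger.info("interpolate_daily: excluded %d pixels with < 2 ages", n_drop)
    if t_start is None:
        t_start = float(model.ages[mask[usable].argmax(axis=1)].min())
    days = t_start + np.arange(n_days, dtype=float)

    n_keep = model.n_samples
    shape = (n_keep, usable.size, n_days) if statistic is None else (usable.size, n_days)
    values = np.zeros(shape)
    for k, pix in enumerate(usable):
        ages, samples = model.trajectories(int(pix))
        daily = np.empty((n_keep, n_days))
        for s in range(n_keep):
            daily[s] = np.interp(days, ages, samples[s])
        daily[:, days < ages[0]] = 0.0  # unformed before first presence
        if statistic is None:
            values[:, k, :] = daily
        elif statistic == "mean":
            values[k] = daily.mean(axis=0)
        elif statistic == "median":
            values[k] = np.median(daily, axis=0)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return DailyTrajectories(
        days=days,
        values=values,
        locations=model.locations[usable],
        pixel_index=usable,
        reference_density=model.reference_density,
    )


@dataclass
class RateField:
    """Per-pixel mineral deposition rate (% of mature density per day)."""

    days: np.ndarray  # (n_days,)
    rates: np.ndarray  # (n_pixels, n_days), >= 0
    locations: np.ndarray
    edj_bin_mm: float
    n_depth_bins: int
    sigma_xy_px: float = 0.0
    sigma_t_days: float = 0.0

    def to_grid(self) -> np.ndarray:
        """Rates on a (n_days, n_depth_bins, n_dist_bins) image stack."""
        cols = np.round(self.locations[:, 0] / self.edj_bin_mm - 0.5).astype(int)
        rows = np.round(self.locations[:, 1] * (self.n_depth_bins - 1)).astype(int)
        grid = np.zeros((self.days.size, self.n_depth_bins, cols.max() + 1))
        grid[:, rows, cols] = self.rates.T
        return grid


def rate_field(
    daily: DailyTrajectories,
    edj_bin_mm: float,
    n_depth_bins: int,
) -> RateField:
    """First difference of the summary trajectory, in %/day of the mature
    density.  Monotone trajectories make every rate non-negative; the sum of
    rates over time telescopes to final minus initial density."""
    if daily.values.ndim != 2:
        raise ValueError("rate_field expects a summary statistic (2D) daily array")
    pct = daily.values / daily.reference_density * 100.0
    rates = np.diff(pct, axis=1, prepend=pct[:, :1])
    return RateField(
        days=daily.days,
        rates=rates,
        locations=daily.locations,
        edj_bin_mm=edj_bin_mm,
        n_depth_bins=n_depth_bins,
    )


@dataclass
class TimeAveragingResult:
    """Per-pixel span (days) between first deposition and near-completion."""

    days_averaged: np.ndarray  # (n_pixels,), NaN where incomplete
    complete: np.ndarray  # (n_pixels,) bool
    locations: np.ndarray

    def band_means(self, edges=(1.0 / 3.0, 2.0 / 3.0)) -> dict[str, float]:
        """Mean averaging time in inner / mid / outer depth bands."""
        depth = self.locations[:, 1]
        out = {}
        for name, lo, hi in (
            ("inner", 0.0, edges[0]),
            ("mid", edges[0], edges[1]),
            ("outer", edges[1], 1.0 + 1e-9),
        ):
            sel = (depth >= lo) & (depth < hi) & self.complete
            out[name] = float(np.mean(self.days_averaged[sel])) if sel.any() else np.nan
        return out


def crossing_times(daily: DailyTrajectories, frac: float) -> np.ndarray:
    """Per-pixel day the summary trajectory first reaches ``frac`` of the
    reference maximum, linearly interpolated between days; NaN if never."""
    if daily.values.ndim != 2:
        raise ValueError("crossing_times expects a summary (2D) daily array")
    threshold = frac * daily.reference_density
    out = np.full(daily.values.shape[0], np.nan)
    for i, traj in enumerate(daily.values):
        done = np.flatnonzero(traj >= threshold)
        if not done.size:
            continue
        j = done[0]
        if j > 0 and traj[j] > traj[j - 1]:
            out[i] = daily.days[j - 1] + (threshold - traj[j - 1]) / (
                traj[j] - traj[j - 1]
            ) * (daily.days[j] - daily.days[j - 1])
        else:
            out[i] = daily.days[j]
    return out


def time_averaging_map(
    daily: DailyTrajectories,
    end_frac: float = 0.85,
) -> TimeAveragingResult:
    """Days between first nonzero density and reaching ``end_frac`` of the
    reference maximum, per pixel, on the summary trajectory.

    This is the window over which blood-chemistry inputs are blended into a
    location's mineral ("time averaging").  Pixels never reaching the end
    fraction within the window are flagged incomplete (NaN).
    """
    if daily.values.ndim != 2:
        raise ValueError("time_averaging_map expects a summary (2D) daily array")
    cross = crossing_times(daily, end_frac)
    n_pix = daily.values.shape[0]
    out = np.full(n_pix, np.nan)
    complete = np.zeros(n_pix, bool)
    for i, traj in enumerate(daily.values):
        nz = np.flatnonzero(traj > 0)
        if nz.size and np.isfinite(cross[i]):
            # floor at 0: sub-day interpolation of an instantaneous rise can
            # place the crossing marginally before the first nonzero day
            out[i] = max(cross[i] - daily.days[nz[0]], 0.0)
            complete[i] = True
    return TimeAveragingResult(
        days_averaged=out, complete=complete, locations=daily.locations
    )


def smooth_rate_field(
    field: RateField, sigma_xy: float = 1.0, sigma_t: float = 8.0
) -> np.ndarray:
    """Gaussian-blurred rate stack (n_days, n_depth, n_dist) for display."""
    grid = field.to_grid()
    if sigma_xy == 0 and sigma_t == 0:
        return grid
    return ndimage.gaussian_filter(grid, sigma=(sigma_t, sigma_xy, sigma_xy))


def export_animation_frames(
    field: RateField,
    out_dir,
    sigma_xy: float = 1.0,
    sigma_t: float = 8.0,
    cmap: str = "jet",
) -> list[Path]:
    """Write one image frame per day of the blurred rate field.

    Frames share a fixed color scale (the 99.5th percentile of the blurred
    stack) so intensity is comparable across time.
    """
    import imageio.v3 as iio
    import matplotlib as mpl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = smooth_rate_field(field, sigma_xy, sigma_t)
    vmax = max(np.percentile(stack, 99.5), 1e-12)
    colormap = mpl.colormaps[cmap]
    paths = []
    for i, frame in enumerate(stack):
        rgba = colormap(np.clip(frame / vmax, 0.0, 1.0))
        img = (rgba[..., :3] * 255).astype(np.uint8)
        p = out_dir / f"rate_{i:04d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths
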