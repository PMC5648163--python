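"""Forward simulator of two-wave enamel mineralization.

Generates ontogenetic series of grayscale enamel sections with known ground
truth, emulating the structure of synchrotron virtual buccal sections of
sheep first molars: ~45 specimens aged between before birth and 540 days,
enamel growing by extension (secretory front advancing along the
enamel-dentin junction, EDJ) and apposition (thickening from the EDJ to the
outer surface), with a partially mineralized secretory deposit followed by
a lagged, diffuse maturation wave that raises density to its mature
maximum.

The simulator works in tooth coordinates: ``x`` is arc distance along the
EDJ from the dentin horn (mm), ``d`` is relative depth through the enamel
(0 at the EDJ, 1 at the outer surface), and ``t`` is age in days.  A pixel
at (x, d) comes into existence when the secretory front has passed x and
apposition has reached its depth; its density then jumps to a fixed
fraction of the mature density and, after a depth-dependent lag, rises
along a logistic ramp to the mature maximum.  Every quantity has a closed
form, so rendered sections can be checked against analytic truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erfinv as _erfinv

from .density_calibration import (
    REFERENCE_MAX_DENSITY,
    CalibrationParams,
    ToothSection,
    density_to_grey,
)
from .growth_curves import GrowthCurveParams, extension_age, extension_length

logger = logging.getLogger("mineralwave")

#: Default extension curve for a synthetic first molar: zero length at the
#: prenatal initiation day (-49), ~29 mm at 100 days, nearly complete by
#: 200 days, mature length 38 mm.  The offset is chosen so the curve passes
#: exactly through (initiation day, 0).
_A, _S, _ELMAX = 22.0, 0.009, 38.0
DEFAULT_EXTENSION = GrowthCurveParams(
    a=_A,
    s=_S,
    o=float(-49.0 + _erfinv((_A - _ELMAX) / _A * -1.0) / _S),
    el_max=_ELMAX,
    curve_kind="extension",
)

#: Zero-intercept calibration lines used when rendering synthetic sections,
#: one per pretend scan batch.  Their grey ranges cover the full density
#: span of forming enamel, including the partially mineralized secretory
#: deposit, so noise-free rendering round-trips exactly.
SYNTHETIC_CALIBRATIONS = {
    1: CalibrationParams(slope=4.0e-5, intercept=0.0, batch_id=1),
    2: CalibrationParams(slope=1.6e-4, intercept=0.0, batch_id=2),
}

_RAMP_STEEPNESS = 8.0  # logistic steepness of the maturation ramp (unitless)


class SimulationError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class WaveModelParams:
    """Parameters of the two-wave forward model.

    Defaults emulate the study conditions of the source ontogenetic series:
    secretory enamel at 25% of mature density (secretion carries 20-30% of
    mature mineral weight), a maturation lag of ~40 days at the EDJ that
    shrinks toward the outer surface, a ~60-day maturation ramp, a mature
    density of 2.62 g/cm^3 and 5% multiplicative measurement noise.
    """

    extension_params: GrowthCurveParams = DEFAULT_EXTENSION
    secretion_density_frac: float = 0.25  # fraction of max density at secretion
    maturation_lag_cuspal: float = 40.0  # days, lag at the EDJ (depth 0)
    lag_depth_gradient: float = 25.0  # days per unit relative depth
    maturation_duration: float = 60.0  # days from onset to completion
    max_density: float = REFERENCE_MAX_DENSITY  # g/cm^3
    # Secretion at a location is brief: the full thickness is deposited in
    # ~10 days, giving the secretory front its steep angle to the EDJ.
    apposition_rate: float = 0.1  # mm/day enamel thickening
    enamel_thickness_mm: float = 1.0  # full thickness (constant profile)
    thickness_profile: Callable[[np.ndarray], np.ndarray] | None = None
    edj_slope: float = 0.15  # image-space slope of the EDJ line (rows/col)
    noise_frac: float = 0.05  # relative measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.secretion_density_frac < 1.0:
            raise SimulationError("secretion_density_frac must lie in (0, 1)")
        if min(self.maturation_lag_cuspal, self.maturation_duration) < 0:
            raise SimulationError("durations must be >= 0")
        if self.max_density <= 0 or self.apposition_rate <= 0:
            raise SimulationError("max_density and apposition_rate must be > 0")
        if self.noise_frac < 0:
            raise SimulationError("noise_frac must be >= 0")

    def thickness(self, x_mm):
        """Full enamel thickness (mm) at EDJ distance ``x_mm``."""
        x_mm = np.asarray(x_mm, dtype=float)
        if self.thickness_profile is not None:
            out = np.asarray(self.thickness_profile(x_mm), dtype=float)
        else:
            out = np.full_like(x_mm, self.enamel_thickness_mm)
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Analytic truth
# ---------------------------------------------------------------------------

def _ramp(u: np.ndarray) -> np.ndarray:
    """Normalized logistic maturation ramp: 0 at u=0, 1 at u=1, monotone."""
    k = _RAMP_STEEPNESS
    u = np.clip(u, 0.0, 1.0)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))  # noqa: E731
    lo, hi = sig(-0.5 * k), sig(0.5 * k)
    return (sig(k * (u - 0.5)) - lo) / (hi - lo)


def _ramp_inverse(y: float) -> float:
    """Inverse of :func:`_ramp` on (0, 1)."""
    k = _RAMP_STEEPNESS
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))  # noqa: E731
    lo, hi = sig(-0.5 * k), sig(0.5 * k)
    p = y * (hi - lo) + lo
    return 0.5 + np.log(p / (1.0 - p)) / k


def secretion_time(params: WaveModelParams, x_mm):
    """Day the secretory front reaches EDJ distance ``x_mm``."""
    return extension_age(x_mm, params.extension_params, clamp=True)


def existence_time(params: WaveModelParams, x_mm, depth_frac):
    """Day the pixel at (x, d) is first deposited by apposition."""
    x_mm = np.asarray(x_mm, dtype=float)
    depth_frac = np.asarray(depth_frac, dtype=float)
    z_mm = depth_frac * params.thickness(x_mm)
    out = secretion_time(params, x_mm) + z_mm / params.apposition_rate
    return float(out) if out.ndim == 0 else out


def maturation_lag(params: WaveModelParams, depth_frac):
    """Lag (days) between local secretion and maturation onset at depth d."""
    depth_frac = np.asarray(depth_frac, dtype=float)
    out = np.maximum(
        0.0, params.maturation_lag_cuspal - params.lag_depth_gradient * depth_frac
    )
    return float(out) if out.ndim == 0 else out


def maturation_onset_time(params: WaveModelParams, x_mm, depth_frac):
    return existence_time(params, x_mm, depth_frac) + maturation_lag(params, depth_frac)


def maturation_completion_time(params: WaveModelParams, x_mm, depth_frac):
    return maturation_onset_time(params, x_mm, depth_frac) + params.maturation_duration


def density_at(params: WaveModelParams, x_mm, depth_frac, t_days):
    """True density (g/cm^3) at tooth coordinate (x, d) and age t.

    Zero before local deposition; jumps to the secretory fraction of the
    mature density at deposition; rises along the logistic maturation ramp
    between onset and completion.  Non-decreasing in t by construction.
    """
    x_mm, depth_frac, t_days = np.broadcast_arrays(
        np.asarray(x_mm, float), np.asarray(depth_frac, float), np.asarray(t_days, float)
    )
    t_exist = existence_time(params, x_mm, depth_frac)
    t_onset = t_exist + maturation_lag(params, depth_frac)
    rho_s = params.secretion_density_frac * params.max_density
    if params.maturation_duration > 0:
        u = (t_days - t_onset) / params.maturation_duration
    else:
        u = np.where(t_days >= t_onset, 1.0, 0.0)
    rho = rho_s + (params.max_density - rho_s) * _ramp(u)
    rho = np.where(t_days >= t_exist, rho, 0.0)
    return float(rho) if rho.ndim == 0 else rho


def crossing_time(params: WaveModelParams, x_mm, depth_frac, frac: float):
    """Day density at (x, d) first reaches ``frac`` of the mature maximum."""
    if frac <= params.secretion_density_frac:
        return existence_time(params, x_mm, depth_frac)
    y = (frac - params.secretion_density_frac) / (1.0 - params.secretion_density_frac)
    if y >= 1.0:
        return maturation_completion_time(params, x_mm, depth_frac)
    u = _ramp_inverse(y)
    return maturation_onset_time(params, x_mm, depth_frac) + u * params.maturation_duration


def landmark_position(
    params: WaveModelParams, age_days: float, frac: float, depth_frac: float = 0.5
) -> float:
    """Farthest EDJ distance (mm) where density at depth ``depth_frac`` has
    reached ``frac`` of the mature maximum by ``age_days``.

    The crossing time is strictly increasing in x (later secretion implies
    later maturation), so the position is found by bisection.  Returns 0 if
    no location qualifies.
    """
    p = params.extension_params
    x_hi = min(extension_length(age_days, p), p.el_max - 1e-6)
    if x_hi <= 0 or crossing_time(params, 0.0, depth_frac, frac) > age_days:
        return 0.0
    if crossing_time(params, x_hi, depth_frac, frac) <= age_days:
        return float(x_hi)
    lo, hi = 0.0, float(x_hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if crossing_time(params, mid, depth_frac, frac) <= age_days:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SyntheticTruth:
    """Gridded ground truth plus the generating parameters."""

    params: WaveModelParams
    x_mm: np.ndarray  # EDJ-distance grid (n_x,)
    depth_frac: np.ndarray  # relative-depth grid (n_d,)
    times: np.ndarray  # age grid, days (n_t,)
    density_field: np.ndarray  # (n_x, n_d, n_t) g/cm^3
    secretion_onset_time: np.ndarray  # (n_x, n_d) days
    maturation_onset_time: np.ndarray  # (n_x, n_d) days
    maturation_completion_time: np.ndarray  # (n_x, n_d) days

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in (
                "x_mm",
                "depth_frac",
                "times",
                "density_field",
                "secretion_onset_time",
                "maturation_onset_time",
                "maturation_completion_time",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["max_density"] = self.params.max_density


def simulate_truth(
    params: WaveModelParams,
    pixel_size_mm: float = 0.046,
    time_step_days: float = 5.0,
    t_min_days: float | None = None,
    t_max_days: float = 540.0,
    n_depth: int = 21,
) -> SyntheticTruth:
    """Evaluate the forward model on a regular (x, depth, time) grid."""
    if pixel_size_mm <= 0 or time_step_days <= 0:
        raise SimulationError("grid spacings must be positive")
    p = params.extension_params
    if t_min_days is None:
        t_min_days = float(np.floor(extension_age(1e-3, p, clamp=True)))
    x = np.arange(0.0, p.el_max - 1e-9, pixel_size_mm)
    d = np.linspace(0.0, 1.0, n_depth)
    t = np.arange(t_min_days, t_max_days + 1e-9, time_step_days)
    X, D = np.meshgrid(x, d, indexing="ij")
    field = density_at(
        params, X[..., None], D[..., None], t[None, None, :]
    )
    truth = SyntheticTruth(
        params=params,
        x_mm=x,
        depth_frac=d,
        times=t,
        density_field=field,
        secretion_onset_time=existence_time(params, X, D),
        maturation_onset_time=maturation_onset_time(params, X, D),
        maturation_completion_time=maturation_completion_time(params, X, D),
    )
    assert np.all(np.diff(field, axis=-1) >= -1e-12), "truth must be monotone in t"
    return truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_section(
    truth: SyntheticTruth,
    age_days: float,
    calib: CalibrationParams,
    noise_frac: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    pixel_size_mm: float = 0.046,
    specimen_id: str = "synthetic",
    molar: str = "M1",
    worn: bool = False,
) -> ToothSection:
    """Render one grayscale section of the simulated tooth at a given age.

    The enamel band lies along a straight EDJ of slope ``edj_slope`` in
    image space; each image pixel is projected onto the EDJ to obtain its
    (x, depth) tooth coordinate and the analytic density is inverted through
    the calibration line.  Grey 0 is reserved for background; formed enamel
    grey values are clipped to [1, 65535] with a logged count of clipped
    pixels.  Noise is multiplicative Gaussian (sd = noise_frac * density)
    truncated at +/-4 sd so densities stay positive.
    """
    params = truth.params
    if age_days < truth.times[0] - 1e-9 or age_days > truth.times[-1] + 1e-9:
        raise SimulationError(
            f"age {age_days} outside simulated range "
            f"[{truth.times[0]}, {truth.times[-1]}]"
        )
    if noise_frac is None:
        noise_frac = params.noise_frac
    rng = np.random.default_rng(seed)

    p = params.extension_params
    m = params.edj_slope
    norm = np.hypot(1.0, m)
    tan_r, tan_c = m / norm, 1.0 / norm  # unit tangent along the EDJ
    nrm_r, nrm_c = -1.0 / norm, m / norm  # unit normal into the enamel

    t_max = params.thickness(np.linspace(0, p.el_max, 64)).max()
    len_px = p.el_max / pixel_size_mm
    r0 = int(np.ceil(t_max / pixel_size_mm)) + 2  # horn row, enamel above
    c0 = 2
    n_rows = int(np.ceil(r0 + m * len_px * tan_c)) + 3
    n_cols = int(np.ceil(c0 + len_px * tan_c)) + 3

    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    vr, vc = (rr - r0) * pixel_size_mm, (cc - c0) * pixel_size_mm
    x = vr * tan_r + vc * tan_c  # mm along the EDJ
    z = vr * nrm_r + vc * nrm_c  # mm above the EDJ

    el_now = extension_length(age_days, p)
    in_band = (x >= 0) & (x <= min(el_now, p.el_max - 1e-6)) & (z >= 0)
    xs = np.clip(x, 0.0, p.el_max - 1e-6)
    thick = params.thickness(xs)
    grown = np.maximum(
        0.0, (age_days - secretion_time(params, xs)) * params.apposition_rate
    )
    local_thick = np.minimum(thick, grown)
    formed = in_band & (z <= local_thick) & (local_thick > 0)

    rho = np.zeros((n_rows, n_cols))
    if formed.any():
        depth = np.zeros_like(z)
        depth[formed] = z[formed] / thick[formed]
        rho_f = density_at(params, xs[formed], depth[formed], age_days)
        if noise_frac > 0:
            eps = rng.standard_normal(rho_f.shape)
            np.clip(eps, -4.0, 4.0, out=eps)
            rho_f = rho_f * (1.0 + noise_frac * eps)
        rho[formed] = rho_f

    grey = np.zeros((n_rows, n_cols))
    g = density_to_grey(rho[formed], calib) if formed.any() else np.empty(0)
    n_clipped = int(np.sum((g < 1.0) | (g > 65535.0)))
    if n_clipped:
        logger.warning(
            "render_section(age=%s): %d formed pixels outside the grey range "
            "of batch %s, clipped", age_days, n_clipped, calib.batch_id,
        )
    grey[formed] = np.clip(g, 1.0, 65535.0)

    return ToothSection(
        specimen_id=specimen_id,
        age_days=float(age_days),
        batch=calib.batch_id,
        molar=molar,
        worn=worn,
        pixels=grey,
        pixel_size_mm=pixel_size_mm,
    )


def simulate_series(
    params: WaveModelParams,
    ages: Sequence[float],
    calibrations: dict[int, CalibrationParams] | None = None,
    seed: int | None = None,
    pixel_size_mm: float = 0.046,
    noise_frac: float | None = None,
    time_step_days: float = 5.0,
) -> tuple[list[ToothSection], SyntheticTruth]:
    """Render one section per age from a single shared ground truth.

    Specimens alternate between the two synthetic scan batches.  Per-specimen
    seeds are spawned deterministically from the master seed, so any specimen
    is reproducible independently of the rest of the series.
    """
    ages = list(ages)
    if not ages:
        raise SimulationError("ages must be non-empty")
    if calibrations is None:
        calibrations = SYNTHETIC_CALIBRATIONS
    if seed is None:
        seed = params.seed
    truth = simulate_truth(
        params,
        pixel_size_mm=pixel_size_mm,
        time_step_days=time_step_days,
        t_max_days=max(540.0, max(ages)),
    )
    batch_ids = sorted(calibrations)
    child_seeds = np.random.SeedSequence(seed).spawn(len(ages))
    sections = []
    for i, (age, ss) in enumerate(zip(ages, child_seeds)):
        batch = batch_ids[i % len(batch_ids)]
        sections.append(
            render_section(
                truth,
                age,
                calibrations[batch],
                noise_frac=noise_frac,
                seed=ss,
                pixel_size_mm=pixel_size_mm,
                specimen_id=f"{int(round(age))}_{batch}_{i:03d}",
            )
        )
    return sections, truth


def write_series(sections: Sequence[ToothSection], truth: SyntheticTruth, out_dir) -> Path:
    """Write sections as 16-bit TIFFs plus a CSV manifest and a truth sidecar.

    Files are named ``<age-days>_<batch>_<id>.tif`` (death day first, then
    scan batch).  Quantization to 16 bits rounds grey values to integers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sec in sections:
        fname = f"{int(round(sec.age_days))}_{sec.batch}_{sec.specimen_id}.tif"
        tifffile.imwrite(
            out_dir / fname, np.round(sec.pixels).astype(np.uint16)
        )
        rows.append(
            dict(
                id=sec.specimen_id,
                age_days=sec.age_days,
                batch=sec.batch,
                molar=sec.molar,
                worn=sec.worn,
                filename=fname,
            )
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    truth.to_hdf5(out_dir / "truth.h5")
    return out_dir / "manifest.csv"


def default_series_ages(n: int = 45, t_max: float = 540.0, seed: int = 0) -> list[float]:
    """Ages-at-death for a synthetic ontogenetic series: n specimens spread
    over [0, t_max] days with mild seeded jitter, sorted ascending."""
    rng = np.random.default_rng(seed)
    base = np.linspace(0.0, t_max, n)
    jitter = rng.uniform(-0.4, 0.4, n) * (t_max / max(n - 1, 1))
    ages = np.clip(base + jitter, 0.0, t_max)
    return sorted(float(a) for a in ages)
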