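"""Per-pixel Metropolis-Hastings sampling of monotone mineralization histories.

Each standardized pixel location is observed once per specimen, at that
specimen's size-modeled age, giving a short noisy cross-sectional series of
densities through developmental time.  The mineralization history rho_m(t)
at the pixel is inferred under a Gaussian measurement likelihood

    log L(rho_d | rho_m) = sum_t -(rho_m(t) - rho_d(t))^2 / (2 sigma_t^2)

with a flat prior over the feasible set: trajectories that are
non-decreasing (enamel density may only increase, by at least 1e-5 g/cm^3
per sample interval) and bounded by a density ceiling.  Sampling uses
Metropolis-Hastings with several independent walkers started from jittered
isotonic fits of the data; a subset of post-burn-in states is retained as
the stored posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.isotonic import IsotonicRegression

from .density_calibration import REFERENCE_MAX_DENSITY

logger = logging.getLogger("mineralwave")

#: Minimum per-interval density increment (g/cm^3): density may only increase.
MIN_INCREMENT = 1e-5

#: Measurement error as a fraction of the reference maximum density.
SIGMA_FRACTION = 0.05

#: Feasible trajectories are capped slightly above the reference maximum.
CEILING_FACTOR = 1.05


class UnusablePixelError(ValueError):
    """Raised when a pixel has too few observations to constrain a history."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``sigma_mode`` selects the error model: "constant" uses
    ``SIGMA_FRACTION * reference`` for every measurement (the default — a
    proportional error would make near-zero early densities implausibly
    precise); "proportional" scales sigma with each measured density,
    floored at 10% of the constant value.
    """

    n_samples: int = 150_000
    n_walkers: int = 4
    n_keep: int = 100
    burn_in_frac: float = 0.5
    target_acceptance: float = 0.25
    sigma_mode: str = "constant"
    sigma_fraction: float = SIGMA_FRACTION
    reference_density: float = REFERENCE_MAX_DENSITY
    min_increment: float = MIN_INCREMENT
    ceiling_factor: float = CEILING_FACTOR
    seed: int = 0

    @property
    def density_ceiling(self) -> float:
        return self.ceiling_factor * self.reference_density


@dataclass
class PixelSeries:
    """Cross-sectional density observations at one standardized location."""

    location: tuple[float, float]  # (EDJ distance mm, relative depth)
    times: np.ndarray  # (n_specimens,) size-modeled ages, strictly increasing
    rho_d: np.ndarray  # (n_specimens,) measured densities; valid where present
    present: np.ndarray  # (n_specimens,) bool: pixel exists in that specimen
    sigma: np.ndarray  # (n_specimens,) per-measurement error, g/cm^3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.rho_d = np.asarray(self.rho_d, float)
        self.present = np.asarray(self.present, bool)
        self.sigma = np.asarray(self.sigma, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing (jitter ties first)")
        if np.any(self.sigma[self.present] <= 0):
            raise ValueError("sigma must be > 0 at every present time")

    @property
    def n_present(self) -> int:
        return int(self.present.sum())


@dataclass
class TrajectoryPosterior:
    """Retained monotone posterior trajectories for one pixel."""

    location: tuple[float, float]
    times: np.ndarray  # present-time grid the samples live on
    samples: np.ndarray  # (n_keep, n_times) g/cm^3
    acceptance_rate: float
    n_total_samples: int
    n_walkers: int
    seed: int

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def band(self, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        """Central credible band at the given level."""
        alpha = 0.5 * (1.0 - level)
        return (
            np.quantile(self.samples, alpha, axis=0),
            np.quantile(self.samples, 1.0 - alpha, axis=0),
        )


def log_likelihood(traj: np.ndarray, series: PixelSeries) -> float:
    """Gaussian log likelihood of a trajectory on the present-time grid.

    ``traj`` holds the modeled density at each present time; absent
    specimens contribute nothing.
    """
    traj = np.asarray(traj, float)
    if traj.shape != (series.n_present,):
        raise ValueError(
            f"trajectory length {traj.shape} does not match the "
            f"{series.n_present} present times"
        )
    d = series.rho_d[series.present]
    s = series.sigma[series.present]
    return float(np.sum(-((traj - d) ** 2) / (2.0 * s**2)))


def propose(
    traj: np.ndarray, step_scale: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Symmetric single-site proposal: Gaussian step at one uniform index.

    Feasibility (monotonicity, minimum increment, bounds) is the caller's
    check — an infeasible candidate gets acceptance probability 0.
    """
    traj = np.asarray(traj, float)
    j = int(rng.integers(traj.size))
    cand = traj.copy()
    cand[j] += step_scale * rng.standard_normal()
    return cand, j


def is_feasible(
    traj: np.ndarray,
    min_increment: float = MIN_INCREMENT,
    lo: float = 0.0,
    hi: float = CEILING_FACTOR * REFERENCE_MAX_DENSITY,
) -> bool:
    """Whether a trajectory lies in the flat prior's support."""
    traj = np.asarray(traj, float)
    if traj[0] < lo or traj[-1] > hi:
        return False
    return bool(np.all(np.diff(traj) >= min_increment - 1e-15))


def _feasible_projection(
    y: np.ndarray, min_increment: float, lo: float, hi: float
) -> np.ndarray:
    """Push a vector into the monotone feasible set with minimal motion."""
    x = np.clip(y.copy(), lo, hi)
    for i in range(1, x.size):  # forward: enforce increments
        x[i] = max(x[i], x[i - 1] + min_increment)
    x = np.minimum(x, hi)
    for i in range(x.size - 1, 0, -1):  # backward: restore increments under cap
        x[i - 1] = min(x[i - 1], x[i] - min_increment)
    x = np.maximum(x, lo)
    return x


@njit(cache=True)
def _mh_chain(
    x: np.ndarray,
    data: np.ndarray,
    inv2sig2: np.ndarray,
    min_inc: float,
    lo: float,
    hi: float,
    burn_in: int,
    step0: float,
    target: float,
    idxs: np.ndarray,
    zs: np.ndarray,
    log_us: np.ndarray,
    keep_at: np.ndarray,
    out: np.ndarray,
):  # pragma: no cover - exercised through sample_pixel
    n = x.size
    n_steps = idxs.size
    step = step0
    n_acc_post = 0
    k = 0
    for i in range(n_steps):
        j = idxs[i]
        xj = x[j]
        cand = xj + step * zs[i]
        lo_j = lo if j == 0 else x[j - 1] + min_inc
        hi_j = hi if j == n - 1 else x[j + 1] - min_inc
        accepted = False
        if lo_j <= cand <= hi_j:
            d = cand - data[j]
            e = xj - data[j]
            dlog = -(d * d - e * e) * inv2sig2[j]
            if dlog >= 0.0 or log_us[i] < dlog:
                x[j] = cand
                accepted = True
        if i < burn_in:
            g = min(0.1, (i + 1.0) ** (-0.6))
            if accepted:
                step *= np.exp(g * (1.0 - target))
            else:
                step *= np.exp(-g * target)
            step = min(max(step, 1e-7), 2.0)
        elif accepted:
            n_acc_post += 1
        if k < keep_at.size and i == keep_at[k]:
            for q in range(n):
                out[k, q] = x[q]
            k += 1
    return n_acc_post, step


def sample_pixel(
    series: PixelSeries,
    config: MCMCConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> TrajectoryPosterior:
    """Sample monotone mineralization histories for one pixel.

    Runs ``n_walkers`` independent chains from isotonic-regression
    initializations jittered per walker, discards the burn-in half of each
    chain (during which the step size is adapted toward the target
    acceptance and then frozen, preserving detailed balance afterwards), and
    retains ``n_keep`` trajectories pooled evenly across walkers by uniform
    thinning.  Deterministic given the seed.
    """
    cfg = config or MCMCConfig()
    if series.n_present < 2:
        raise UnusablePixelError(
            f"pixel {series.location} observed in {series.n_present} specimens; "
            "need >= 2"
        )
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    data = series.rho_d[series.present].astype(float)
    sig = series.sigma[series.present].astype(float)
    times = series.times[series.present]
    n_t = data.size
    lo, hi = 0.0, cfg.density_ceiling
    n_per = cfg.n_samples // cfg.n_walkers
    burn_in = int(cfg.burn_in_frac * n_per)
    keep_per = np.full(cfg.n_walkers, cfg.n_keep // cfg.n_walkers)
    keep_per[: cfg.n_keep % cfg.n_walkers] += 1

    iso = IsotonicRegression(y_min=lo, y_max=hi, increasing=True)
    base = iso.fit_transform(np.arange(n_t), np.clip(data, lo, hi))

    kept = []
    acc_total = 0
    for w, child in enumerate(ss.spawn(cfg.n_walkers)):
        rng = np.random.default_rng(child)
        x0 = _feasible_projection(
            base + 0.02 * cfg.reference_density * rng.standard_normal(n_t),
            cfg.min_increment, lo, hi,
        )
        idxs = rng.integers(0, n_t, n_per)
        zs = rng.standard_normal(n_per)
        log_us = np.log(rng.random(n_per))
        n_k = int(keep_per[w])
        keep_at = np.unique(
            np.linspace(burn_in, n_per - 1, max(n_k, 1)).round().astype(np.int64)
        )
        out = np.empty((keep_at.size, n_t))
        n_acc, _ = _mh_chain(
            x0.copy(), data, 1.0 / (2.0 * sig**2), cfg.min_increment, lo, hi,
            burn_in, 0.1 * cfg.reference_density, cfg.target_acceptance,
            idxs, zs, log_us, keep_at, out,
        )
        acc_total += n_acc
        kept.append(out[-n_k:] if n_k else out[:0])

    samples = np.vstack(kept)
    post_steps = cfg.n_walkers * (n_per - burn_in)
    return TrajectoryPosterior(
        location=series.location,
        times=times,
        samples=samples,
        acceptance_rate=acc_total / max(post_steps, 1),
        n_total_samples=cfg.n_samples,
        n_walkers=cfg.n_walkers,
        seed=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
    )


def run_all_pixels(
    series_list: list[PixelSeries],
    config: MCMCConfig | None = None,
    progress_every: int = 500,
) -> tuple[list[TrajectoryPosterior], list[PixelSeries]]:
    """Sample every usable pixel independently, in list order.

    Pixels are processed in the stable order given (the stack builder emits
    row-major order over EDJ-distance then depth); per-pixel seeds are
    spawned from the master seed, so results are bit-reproducible and
    independent of which other pixels are in the run.  Returns the
    posteriors and the subset of usable series, aligned.
    """
    cfg = config or MCMCConfig()
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(len(series_list))
    posteriors: list[TrajectoryPosterior] = []
    usable: list[PixelSeries] = []
    n_skipped = 0
    for i, (series, child) in enumerate(zip(series_list, children)):
        try:
            post = sample_pixel(series, cfg, seed=child)
        except UnusablePixelError:
            n_skipped += 1
            continue
        posteriors.append(post)
        usable.append(series)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("sampled %d / %d pixels", i + 1, len(series_list))
    if n_skipped:
        logger.info("skipped %d pixels with < 2 observations", n_skipped)
    return posteriors, usable


def build_pixel_series(
    flats,
    records,
    config: MCMCConfig | None = None,
    horn_offsets_mm: dict[str, float] | None = None,
    distance_stride: int = 1,
    depth_stride: int = 1,
) -> list[PixelSeries]:
    """Assemble per-pixel observation series from a flattened specimen stack.

    ``flats`` are FlattenedEnamel grids sharing depth binning and bin width;
    ``records`` are SpecimenRecords carrying each specimen's size-modeled
    age.  Ties in t_m are broken with a deterministic jitter of 1e-6 day per
    rank so every series has a strictly increasing time grid.  Worn
    specimens' grids are shifted cuspally by their horn offset.  Strides
    subsample the pixel lattice for scaled-down runs.
    """
    cfg = config or MCMCConfig()
    by_id = {f.specimen_id: f for f in flats}
    recs = sorted(records, key=lambda r: r.t_m)
    t = np.array([r.t_m for r in recs], float)
    ranks = np.arange(len(recs))
    t = t + 1e-6 * ranks  # deterministic tie-jitter
    for i in range(1, t.size):  # guard exact collisions after jitter
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1e-6

    n_depth = {f.n_depth_bins for f in flats}
    bin_mm = {round(f.edj_bin_mm, 9) for f in flats}
    if len(n_depth) != 1 or len(bin_mm) != 1:
        raise ValueError("flattened specimens must share depth binning and bin width")
    n_depth = n_depth.pop()
    offsets = horn_offsets_mm or {}
    off_bins = {
        sid: int(round(off / flats[0].edj_bin_mm)) for sid, off in offsets.items()
    }
    n_dist = max(
        (np.flatnonzero(f.valid_columns)[-1] + 1 if f.valid_columns.any() else 0)
        + off_bins.get(f.specimen_id, 0)
        for f in flats
    )

    depth_grid = np.linspace(0.0, 1.0, n_depth)
    series_list: list[PixelSeries] = []
    for ix in range(0, n_dist, distance_stride):
        for idp in range(0, n_depth, depth_stride):
            rho = np.zeros(len(recs))
            present = np.zeros(len(recs), bool)
            for k, rec in enumerate(recs):
                flat = by_id.get(rec.specimen_id)
                if flat is None:
                    continue
                col = ix - off_bins.get(rec.specimen_id, 0)
                if col < 0 or col >= flat.densities.shape[0]:
                    continue
                if flat.mask[col, idp]:
                    present[k] = True
                    rho[k] = flat.densities[col, idp]
            if cfg.sigma_mode == "proportional":
                sigma = np.maximum(
                    cfg.sigma_fraction * rho,
                    0.1 * cfg.sigma_fraction * cfg.reference_density,
                )
            else:
                sigma = np.full(len(recs), cfg.sigma_fraction * cfg.reference_density)
            series_list.append(
                PixelSeries(
                    location=((ix + 0.5) * flats[0].edj_bin_mm, float(depth_grid[idp])),
                    times=t,
                    rho_d=rho,
                    present=present,
                    sigma=sigma,
                )
            )
    return series_list
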