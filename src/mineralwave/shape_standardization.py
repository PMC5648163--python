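"""Standardized tooth coordinates: EDJ tracing, flattening, landmarks.

Sections from different specimens are compared in a shared coordinate
system: arc distance along the enamel-dentin junction (EDJ) from the dentin
horn, and relative depth through the enamel (0 at the EDJ, 1 at the outer
surface).  Each density map is flattened by resampling along local normals
to the traced EDJ, and per-specimen growth landmarks are read off the
flattened grid: extension length (how far secretion has progressed) and the
positions where mid-depth density has reached 40% (maturation onset) and
85% (maturation completion) of the reference maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage import measure

from .density_calibration import REFERENCE_MAX_DENSITY, DensityMap

logger = logging.getLogger("mineralwave")

#: Density fractions defining the maturation landmarks.
ONSET_FRACTION = 0.40
COMPLETION_FRACTION = 0.85


class StandardizationError(ValueError):
    """Raised for untraceable or geometrically invalid sections."""


@dataclass
class EdjPath:
    """Ordered EDJ pixel path from the dentin horn to the cervical end."""

    points: np.ndarray  # (n, 2) float (row, col) pixel coordinates
    arc_mm: np.ndarray  # (n,) cumulative arc length, strictly increasing
    pixel_size_mm: float

    @property
    def length_mm(self) -> float:
        return float(self.arc_mm[-1])


@dataclass
class FlattenedEnamel:
    """Densities resampled onto (EDJ-distance bin, relative-depth bin)."""

    densities: np.ndarray  # (n_dist_bins, n_depth_bins) g/cm^3
    mask: np.ndarray  # same shape, True where enamel exists
    edj_bin_mm: float  # mm of EDJ arc per distance bin
    n_depth_bins: int
    surface_mm: np.ndarray  # (n_dist_bins,) local enamel thickness, mm
    specimen_id: str = ""
    age_days: float = np.nan

    @property
    def valid_columns(self) -> np.ndarray:
        return self.mask.any(axis=1)


@dataclass
class LandmarkSet:
    """Growth landmarks of one flattened specimen (mm along the EDJ)."""

    e_l: float  # extension length
    onset_pos: float  # farthest 40%-density position at mid depth
    completion_pos: float  # farthest 85%-density position at mid depth
    reference_density: float
    age_days: float
    specimen_id: str = ""
    horn_offset_mm: float = 0.0


def trace_edj(dmap: DensityMap, horn_hint: tuple[int, int] | None = None) -> EdjPath:
    """Trace the dentin-facing boundary of the enamel mask.

    The EDJ is the inner (dentin-side, by convention the bottom) boundary of
    the enamel band: for each image column intersecting the mask, the
    bottom-most masked pixel.  The path is ordered starting from the end
    nearest ``horn_hint`` (default: the leftmost, cuspal end) and must be
    connected — a fragmented mask is an error listing its components.
    """
    mask = np.asarray(dmap.mask, bool)
    if not mask.any():
        raise StandardizationError("enamel mask is empty")
    labels, n_comp = measure.label(mask, connectivity=2, return_num=True)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        main = int(np.argmax(sizes)) + 1
        # Isolated specks (discretization at the thin wedge tip) are dropped;
        # comparable fragments mean a genuinely split section.
        speck_limit = max(9, 0.005 * sizes.max())
        if np.sum(sizes > speck_limit) > 1:
            raise StandardizationError(
                f"enamel mask is disconnected: {n_comp} components with pixel "
                f"counts {sorted(sizes.tolist(), reverse=True)}"
            )
        logger.warning(
            "trace_edj: dropped %d speck component(s) of sizes %s",
            n_comp - 1,
            sorted(int(s) for i, s in enumerate(sizes, 1) if i != main),
        )
        mask = labels == main
    cols = np.flatnonzero(mask.any(axis=0))
    rows = np.array([np.max(np.flatnonzero(mask[:, c])) for c in cols])
    points = np.column_stack([rows, cols]).astype(float)

    start_left = True
    if horn_hint is not None:
        hh = np.asarray(horn_hint, float)
        d_left = np.hypot(*(points[0] - hh))
        d_right = np.hypot(*(points[-1] - hh))
        start_left = d_left <= d_right
    if not start_left:
        points = points[::-1]

    steps = np.hypot(*np.diff(points, axis=0).T)
    jumps = np.flatnonzero(steps > np.sqrt(2.0) + 1e-9)
    if jumps.size:
        # A short ragged tail (the sub-pixel wedge at the secretory front) is
        # truncated; a break in the body of the path is a real discontinuity.
        first = int(jumps[0])
        n_drop = len(points) - (first + 1)
        if n_drop > max(3, 0.05 * len(points)):
            raise StandardizationError(
                f"EDJ path breaks between columns {int(points[first, 1])} and "
                f"{int(points[first + 1, 1])} (step {steps[first]:.2f} px)"
            )
        logger.warning("trace_edj: truncated %d ragged tip column(s)", n_drop)
        points = points[: first + 1]
    # A staircase boundary overestimates arc length (diagonal jumps); smooth
    # the coordinates before integrating so arcs match the underlying curve.
    # Savitzky-Golay with a linear kernel reproduces straight boundaries
    # exactly, endpoints included.
    win = min(9, len(points))
    if win >= 3:
        smooth = np.column_stack(
            [
                savgol_filter(points[:, 0], win, polyorder=1, mode="interp"),
                savgol_filter(points[:, 1], win, polyorder=1, mode="interp"),
            ]
        )
    else:
        smooth = points.astype(float)
    arc = (
        np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(smooth, axis=0).T))])
        * dmap.pixel_size_mm
    )
    return EdjPath(points=smooth, arc_mm=arc, pixel_size_mm=dmap.pixel_size_mm)


def _fill_background(densities: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace background values with their nearest enamel value so that
    bilinear sampling near the mask edge does not bleed zeros in."""
    if mask.all():
        return densities
    idx = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return densities[tuple(idx)]


def flatten(
    dmap: DensityMap,
    edj: EdjPath,
    n_depth_bins: int = 20,
    max_thickness_mm: float | None = None,
) -> FlattenedEnamel:
    """Resample a density map into standardized tooth coordinates.

    For each EDJ arc-length bin (one pixel of arc per bin), densities are
    sampled by linear interpolation along the local normal from the EDJ
    (depth 0) to the current outer enamel surface (depth 1), located by
    marching the normal until it exits the mask.  Bins beyond formed enamel,
    or whose normal immediately leaves the mask, are masked out (counted and
    logged).
    """
    px = dmap.pixel_size_mm
    if max_thickness_mm is None:
        max_thickness_mm = 0.25 * min(dmap.mask.shape) * px + 10 * px
    n_bins = int(np.floor(edj.length_mm / px)) + 1
    centers = (np.arange(n_bins) + 0.5) * px
    centers = np.minimum(centers, edj.arc_mm[-1])

    # Smooth the traced path before differentiating: a staircase boundary has
    # noisy per-pixel tangents but a stable running direction.
    win = min(9, len(edj.points))
    if win >= 3:
        sm_r = savgol_filter(edj.points[:, 0], win, polyorder=1, mode="interp")
        sm_c = savgol_filter(edj.points[:, 1], win, polyorder=1, mode="interp")
    else:
        sm_r, sm_c = edj.points[:, 0], edj.points[:, 1]
    pr = np.interp(centers, edj.arc_mm, sm_r)
    pc = np.interp(centers, edj.arc_mm, sm_c)
    tr = np.gradient(pr, centers, edge_order=1)
    tc = np.gradient(pc, centers, edge_order=1)
    tnorm = np.hypot(tr, tc)
    tnorm[tnorm == 0] = 1.0
    tr, tc = tr / tnorm, tc / tnorm
    # Two candidate normals; enamel lies on the side with more mask support.
    nr, nc = -tc, tr
    mask_f = dmap.mask.astype(float)
    probe = 3.0  # pixels
    up = ndimage.map_coordinates(mask_f, [pr + probe * nr, pc + probe * nc], order=1)
    dn = ndimage.map_coordinates(mask_f, [pr - probe * nr, pc - probe * nc], order=1)
    if dn.sum() > up.sum():
        nr, nc = -nr, -nc

    # March along the normal from the boundary pixel centers (reliably inside
    # the mask) to find the current outer surface per bin.  The actual EDJ —
    # the 0.5-level mask contour — sits half a pixel dentin-ward of the pixel
    # centers, so thickness and depth are measured from there.
    step = 0.5  # pixels
    n_steps = int(np.ceil(max_thickness_mm / px / step)) + 2
    jj = np.arange(n_steps) * step
    rr = pr[:, None] + jj[None, :] * nr[:, None]
    cc = pc[:, None] + jj[None, :] * nc[:, None]
    mask_vals = ndimage.map_coordinates(mask_f, [rr, cc], order=1, cval=0.0)
    inside = mask_vals >= 0.5
    # Outer surface = end of the contiguous in-mask run, with the final
    # half-step refined by interpolating the 0.5 mask crossing.
    run = np.cumprod(inside, axis=1)
    run_len = run.sum(axis=1)  # samples in the run, j = 0 .. run_len-1
    j_last = np.clip(run_len - 1, 0, n_steps - 1)
    rows_idx = np.arange(run_len.size)
    v_in = mask_vals[rows_idx, j_last]
    v_out = mask_vals[rows_idx, np.clip(j_last + 1, 0, n_steps - 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.clip((v_in - 0.5) / (v_in - v_out), 0.0, 1.0)
    frac[~np.isfinite(frac)] = 0.5
    surf_px = 0.5 + (j_last + frac) * step  # pixels, EDJ contour -> surface
    n_unreached = int(np.sum(inside[:, -1] & (run[:, -1] > 0)))
    if n_unreached:
        logger.warning(
            "flatten: %d bins hit the marching limit before the enamel surface",
            n_unreached,
        )
    valid = surf_px > step  # at least one full marching step of enamel

    filled = _fill_background(np.asarray(dmap.densities, float), dmap.mask)
    depths = np.linspace(0.0, 1.0, n_depth_bins)
    # Depth 0 sits on the EDJ contour and depth 1 on the current surface;
    # background filling keeps face samples from bleeding zeros in.
    zz = depths[None, :] * surf_px[:, None] - 0.5  # pixels from path centers
    sr = pr[:, None] + zz * nr[:, None]
    sc = pc[:, None] + zz * nc[:, None]
    dens = ndimage.map_coordinates(filled, [sr, sc], order=1, cval=0.0)
    dens[~valid] = 0.0
    mask_out = np.repeat(valid[:, None], n_depth_bins, axis=1)
    return FlattenedEnamel(
        densities=dens,
        mask=mask_out,
        edj_bin_mm=px,
        n_depth_bins=n_depth_bins,
        surface_mm=surf_px * px,
        specimen_id=dmap.specimen_id,
        age_days=dmap.age_days,
    )


def mid_depth_profile(flat: FlattenedEnamel, median_window: int = 3) -> np.ndarray:
    """Density profile at relative depth 0.5, median-filtered along the EDJ.

    Depth 0.5 is interpolated between the two bracketing depth bins; a short
    median filter suppresses isolated noisy bins without shifting threshold
    crossings systematically.  Invalid columns are NaN.
    """
    depths = np.linspace(0.0, 1.0, flat.n_depth_bins)
    prof = np.array(
        [np.interp(0.5, depths, row) for row in flat.densities], dtype=float
    )
    valid = flat.valid_columns
    if valid.any() and median_window > 1:
        prof_v = ndimage.median_filter(prof[valid], size=median_window, mode="nearest")
        prof = prof.copy()
        prof[valid] = prof_v
    prof[~valid] = np.nan
    return prof


def measure_landmarks(
    flat: FlattenedEnamel,
    onset_frac: float = ONSET_FRACTION,
    completion_frac: float = COMPLETION_FRACTION,
    reference_density: float = REFERENCE_MAX_DENSITY,
) -> LandmarkSet:
    """Extract extension length and maturation landmark positions.

    ``e_l`` is the arc length of the farthest masked-in distance bin; the
    onset (completion) position is the arc length of the farthest bin whose
    mid-depth density reaches ``onset_frac`` (``completion_frac``) of the
    reference density.  Degenerate cases return 0 rather than erroring.
    """
    valid = flat.valid_columns
    if not valid.any():
        raise StandardizationError("flattened grid has no masked-in columns")
    # Positions are reported at bin centers (half-open bins of one pixel of
    # arc), which keeps the quantization error zero-mean.
    e_l = (np.flatnonzero(valid)[-1] + 0.5) * flat.edj_bin_mm
    prof = mid_depth_profile(flat)

    def farthest(threshold: float) -> float:
        qual = np.flatnonzero(np.nan_to_num(prof, nan=-np.inf) >= threshold)
        return 0.0 if qual.size == 0 else (qual[-1] + 0.5) * flat.edj_bin_mm

    onset_pos = farthest(onset_frac * reference_density)
    completion_pos = farthest(completion_frac * reference_density)
    return LandmarkSet(
        e_l=float(e_l),
        onset_pos=float(min(onset_pos, e_l)),
        completion_pos=float(min(completion_pos, onset_pos, e_l)),
        reference_density=reference_density,
        age_days=flat.age_days,
        specimen_id=flat.specimen_id,
    )


def estimate_horn_offset(
    worn: FlattenedEnamel, references: list[FlattenedEnamel]
) -> float:
    """Estimate cuspal arc length lost to wear (mm).

    The worn specimen's mid-depth profile is slid along the profile of the
    unworn reference closest in apparent developmental stage (smallest
    extension length still at least as long as the worn specimen's apparent
    length); the least-squares-optimal shift is the lost arc.  Landmark
    positions for the worn specimen should be reported with this offset
    added.
    """
    worn_prof = mid_depth_profile(worn)
    worn_valid = np.flatnonzero(worn.valid_columns)
    if worn_valid.size == 0:
        raise StandardizationError("worn specimen has no enamel columns")
    w = worn_prof[worn_valid[0] : worn_valid[-1] + 1]
    n_w = w.size

    candidates = []
    for ref in references:
        ref_valid = np.flatnonzero(ref.valid_columns)
        if ref_valid.size == 0:
            continue
        n_r = ref_valid[-1] + 1
        if n_r >= n_w:
            candidates.append((n_r, ref))
    if not candidates:
        raise StandardizationError(
            "no unworn reference is at least as developed as the worn specimen"
        )
    n_r, ref = min(candidates, key=lambda t: t[0])
    r_prof = mid_depth_profile(ref)[:n_r]

    best_k, best_sse = 0, np.inf
    for k in range(n_r - n_w + 1):
        seg = r_prof[k : k + n_w]
        diff = seg - w
        ok = np.isfinite(diff)
        if ok.sum() < max(3, n_w // 4):
            continue
        sse = float(np.mean(diff[ok] ** 2))
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k * worn.edj_bin_mm


def save_flattened(flats: list[FlattenedEnamel], path) -> None:
    """Write flattened sections to HDF5, one group per specimen."""
    import h5py

    with h5py.File(path, "w") as f:
        for flat in flats:
            g = f.create_group(flat.specimen_id)
            g.create_dataset("densities", data=flat.densities)
            g.create_dataset("mask", data=flat.mask)
            g.create_dataset("surface_mm", data=flat.surface_mm)
            g.attrs["edj_bin_mm"] = flat.edj_bin_mm
            g.attrs["n_depth_bins"] = flat.n_depth_bins
            g.attrs["age_days"] = flat.age_days


def load_flattened(path) -> list[FlattenedEnamel]:
    import h5py

    flats = []
    with h5py.File(path, "r") as f:
        for sid in f:
            g = f[sid]
            flats.append(
                FlattenedEnamel(
                    densities=g["densities"][()],
                    mask=g["mask"][()].astype(bool),
                    edj_bin_mm=float(g.attrs["edj_bin_mm"]),
                    n_depth_bins=int(g.attrs["n_depth_bins"]),
                    surface_mm=g["surface_mm"][()],
                    specimen_id=sid,
                    age_days=float(g.attrs["age_days"]),
                )
            )
    flats.sort(key=lambda x: x.age_days)
    return flats
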