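"""Integrated-Gaussian (error-function) growth curves for crown formation.

Enamel extension — the progress of the secretory front along the
enamel-dentin junction (EDJ) — is modeled as a sigmoid error function of
age, chosen over exponential or logistic forms because herbivore molar
extension rates peak shortly after initiation and decline thereafter.  The
forward curve is

    e_l(t) = e_lmax - a + a * erf(s*t - o*s)

with amplitude ``a`` (mm), slope ``s`` (1/day), offset ``o`` (days) and
mature maximum length ``e_lmax`` (mm).  Its closed-form inverse re-assigns a
size-modeled age to a specimen from its measured extension length:

    t_m = [erfinv((a + e_l - e_lmax) / a) + o*s] / s

The same family describes the progress of maturation onset (40% density)
and completion (85% density) along the EDJ.  Fitting uses a seeded
Latin-hypercube multistart global stage followed by constrained local
refinement, with a hard constraint tying the curve to the histologically
determined crown initiation day.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf, erfinv
from scipy.stats import qmc

logger = logging.getLogger("mineralwave")

#: Default crown initiation days relative to birth: first molars initiate
#: prenatally, second molars postnatally (calcein-validated).
M1_INITIATION_DAY = -49.0
M2_INITIATION_DAY = 84.0

#: Tolerated curve length at initiation (mm); a few pixels at 46 um.
INITIATION_EPSILON_MM = 0.25


class GrowthCurveError(ValueError):
    """Raised for invalid growth-curve parameters or unfittable data."""


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters of one error-function growth curve.

    ``curve_kind`` labels which landmark the curve tracks: the secretory
    front ("extension"), the 40% density front ("onset"), or the 85% density
    front ("completion").
    """

    a: float  # amplitude, mm
    s: float  # slope, 1/day
    o: float  # offset, days
    el_max: float  # mature maximum EDJ length, mm
    curve_kind: str = "extension"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.s > 0 and self.el_max > 0):
            raise GrowthCurveError(
                f"require a > 0, s > 0, el_max > 0; got a={self.a}, s={self.s}, "
                f"el_max={self.el_max}"
            )


@dataclass
class FitReport:
    """Diagnostics from a growth-curve fit."""

    params: GrowthCurveParams
    rss: float
    residuals_mm: np.ndarray
    n_points: int
    initiation_day: float
    initiation_length_mm: float
    seed: int

    def to_record(self) -> dict:
        rec = asdict(self.params)
        rec.update(
            rss=float(self.rss),
            n_points=int(self.n_points),
            initiation_day=float(self.initiation_day),
            initiation_length_mm=float(self.initiation_length_mm),
            seed=int(self.seed),
        )
        return rec


def extension_length(t, p: GrowthCurveParams):
    """Forward growth curve: landmark position (mm) at age ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    out = p.el_max - p.a + p.a * erf(p.s * t - p.o * p.s)
    return float(out) if out.ndim == 0 else out


def extension_rate(t, p: GrowthCurveParams):
    """Instantaneous growth rate de_l/dt (mm/day); peaks at t = o."""
    t = np.asarray(t, dtype=float)
    u = p.s * t - p.o * p.s
    out = p.a * p.s * (2.0 / np.sqrt(np.pi)) * np.exp(-(u**2))
    return float(out) if out.ndim == 0 else out


def extension_age(e_l, p: GrowthCurveParams, clamp: bool = False):
    """Size-modeled age t_m (days) at which the curve reaches length ``e_l``.

    Closed-form inverse of :func:`extension_length`.  The erfinv argument
    ``(a + e_l - el_max) / a`` must lie in the open interval (-1, 1), i.e.
    ``el_max - 2a < e_l < el_max``; outside it a domain error is raised
    unless ``clamp`` is set (diagnostics/plotting only), in which case the
    argument is clamped to +/-(1 - 1e-9).
    """
    e_l = np.asarray(e_l, dtype=float)
    arg = (p.a + e_l - p.el_max) / p.a
    if clamp:
        arg = np.clip(arg, -1.0 + 1e-9, 1.0 - 1e-9)
    elif np.any(arg <= -1.0) or np.any(arg >= 1.0):
        raise GrowthCurveError(
            "extension length outside the invertible range "
            f"({p.el_max - 2 * p.a:.3f}, {p.el_max:.3f}) mm"
        )
    out = (erfinv(arg) + p.o * p.s) / p.s
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _rss(theta: np.ndarray, ages: np.ndarray, pos: np.ndarray, el_max: float) -> float:
    a, s, o = theta
    pred = el_max - a + a * erf(s * ages - o * s)
    r = pos - pred
    return float(r @ r)


def _curve_at_init(theta: np.ndarray, el_max: float, t0: float) -> float:
    a, s, o = theta
    return el_max - a + a * erf(s * t0 - o * s)


def fit_growth_curve(
    points: Sequence[tuple[float, float]],
    el_max: float | None = None,
    initiation_day: float = M1_INITIATION_DAY,
    curve_kind: str = "extension",
    n_starts: int = 200,
    n_refine: int = 6,
    init_epsilon_mm: float = INITIATION_EPSILON_MM,
    initiation_mode: str | None = None,
    seed: int = 0,
) -> FitReport:
    """Fit (a, s, o) of an error-function growth curve to landmark data.

    Parameters
    ----------
    points
        ``(age_days, position_mm)`` pairs, one per specimen.  Residuals are
        computed in position space (position is the measured quantity at a
        known death age), which keeps the objective defined even for
        near-complete teeth where the age-space inverse is singular.
    el_max
        Mature maximum length (mm); defaults to the largest observed
        position, the natural plug-in for the longest specimen.
    initiation_day
        Day the crown initiates (histologically determined; -49 days for
        first molars, +84 for second molars).
    initiation_mode
        How the initiation day constrains the fit.  "pin" (default for
        extension curves) forces the curve through zero length at the
        initiation day, which is what crown initiation means for the
        secretory front and is essential for identifiability: without it
        the (a, s, o) likelihood has a flat ridge.  "ceiling" (default for
        maturation onset/completion curves, whose fronts start moving only
        after a lag) merely caps the curve at ``init_epsilon_mm`` there.
    n_starts, n_refine
        Size of the Latin-hypercube global stage and the number of best
        starts passed to constrained local refinement.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GrowthCurveError(
            f"need >= 3 (age, position) points to fit a 3-parameter curve, "
            f"got {0 if pts.ndim != 2 else pts.shape[0]}"
        )
    ages, pos = pts[:, 0], pts[:, 1]
    if np.ptp(ages) <= 0:
        raise GrowthCurveError("ages must span a nontrivial range")
    if el_max is None:
        el_max = float(pos.max())
    if el_max <= 0:
        raise GrowthCurveError("el_max must be positive")

    if initiation_mode is None:
        initiation_mode = "pin" if curve_kind == "extension" else "ceiling"
    if initiation_mode not in ("pin", "ceiling"):
        raise GrowthCurveError(f"unknown initiation_mode {initiation_mode!r}")

    age_hi = float(ages.max())
    lo = np.array([0.25 * el_max, 1e-4, initiation_day])
    hi = np.array([2.0 * el_max, 0.05, age_hi])

    def init_len(th):
        return _curve_at_init(th, el_max, initiation_day)

    # Global stage: seeded Latin-hypercube sweep of the (a, s, o) box,
    # penalizing initiation-constraint violation so infeasible basins rank low.
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    if initiation_mode == "pin":
        penalty = lambda th: init_len(th) ** 2  # noqa: E731
    else:
        penalty = lambda th: max(0.0, init_len(th) - init_epsilon_mm) ** 2  # noqa: E731
    scores = np.array(
        [_rss(th, ages, pos, el_max) + 1e4 * penalty(th) for th in starts]
    )
    order = np.argsort(scores)[:n_refine]

    feas_tol = 1e-3  # mm of curve length at the initiation day
    if initiation_mode == "pin":
        cons = [{"type": "eq", "fun": init_len}]

        def feasible(th):
            return abs(init_len(th)) <= 2 * feas_tol

    else:
        cons = [{"type": "ineq", "fun": lambda th: init_epsilon_mm - init_len(th)}]

        def feasible(th):
            return init_len(th) <= init_epsilon_mm + feas_tol

    bounds = list(zip(lo, hi))
    best = None
    for idx in order:
        try:
            res = minimize(
                _rss,
                starts[idx],
                args=(ages, pos, el_max),
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 300, "ftol": 1e-14},
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if not np.all(res.x > 0) or not feasible(res.x):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise GrowthCurveError(
            f"no start satisfied the initiation constraint "
            f"({initiation_mode} at day {initiation_day}) for {curve_kind}"
        )

    a, s, o = best.x
    params = GrowthCurveParams(a=a, s=s, o=o, el_max=el_max, curve_kind=curve_kind)
    residuals = pos - extension_length(ages, params)
    return FitReport(
        params=params,
        rss=float(residuals @ residuals),
        residuals_mm=residuals,
        n_points=len(ages),
        initiation_day=initiation_day,
        initiation_length_mm=float(extension_length(initiation_day, params)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Age re-assignment
# ---------------------------------------------------------------------------

@dataclass
class SpecimenRecord:
    """Per-specimen ages and landmarks used for model time registration."""

    specimen_id: str
    chronological_age: float  # days at death
    e_l: float  # measured extension length, mm
    t_m: float = np.nan  # size-modeled age, days
    onset_pos: float = np.nan
    completion_pos: float = np.nan


def reassign_ages(
    records: Sequence[SpecimenRecord],
    extension_fit: GrowthCurveParams,
    el_epsilon_mm: float = 1e-6,
) -> list[SpecimenRecord]:
    """Assign size-modeled ages t_m = extension_age(e_l) to each specimen.

    Specimens at or beyond ``el_max - el_epsilon_mm`` keep their
    chronological age: once growth has ceased, size carries no age
    information and the inverse is singular.  Returns records sorted by t_m.
    """
    out = []
    for rec in records:
        if rec.e_l >= extension_fit.el_max - el_epsilon_mm:
            t_m = rec.chronological_age
        else:
            t_m = extension_age(rec.e_l, extension_fit, clamp=True)
        out.append(
            SpecimenRecord(
                specimen_id=rec.specimen_id,
                chronological_age=rec.chronological_age,
                e_l=rec.e_l,
                t_m=float(t_m),
                onset_pos=rec.onset_pos,
                completion_pos=rec.completion_pos,
            )
        )
    out.sort(key=lambda r: r.t_m)
    return out


def save_fits(fits: dict[str, FitReport], path) -> None:
    """Serialize fit reports as a JSON record keyed by curve kind."""
    payload = {kind: rep.to_record() for kind, rep in fits.items()}
    for rec in payload.values():
        rec.pop("residuals_mm", None)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def load_fits(path) -> dict[str, GrowthCurveParams]:
    with open(path) as f:
        payload = json.load(f)
    return {
        kind: GrowthCurveParams(
            a=rec["a"], s=rec["s"], o=rec["o"], el_max=rec["el_max"],
            curve_kind=rec.get("curve_kind", kind),
        )
        for kind, rec in payload.items()
    }
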