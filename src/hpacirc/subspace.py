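"""Accept-reject characterization of the regulatory parameter subspace.

The three regulatory parameters — hypothalamic feedback constant ``K_p1``,
pituitary feedback constant ``K_p2`` and adrenal sensitivity ``k_p3`` — are
sampled over a box (log-uniform Sobol by default), each triple is simulated
to its entrained cycle, and triples whose CORT cosinor lies within +/-1 SD
of the calibration target are retained.  Chronic stress is represented by
an elevated CRH drive ``k_p1``; resampling under elevated drive yields the
allostatically adapted subspaces.

The retained set approximates a 2-manifold in (K_p1, K_p2, k_p3) space; its
area is estimated by Delaunay-triangulating the (K_p1, K_p2) projection,
restricting to an alpha-shape of the accepted region, lifting each triangle
to 3D via the k_p3 coordinate, and summing triangle areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import qmc

from .cosinor import CalibrationTarget, CosinorFit, fit_cosinor, passes_calibration
from .errors import DegenerateGeometry, EmptySubspaceWarning, NonConvergence
from .params import LightSchedule, ModelParameters
from .simulate import default_initial_state, integrate, integrate_to_limit_cycle

__all__ = [
    "StressCondition",
    "SamplingBox",
    "AcceptedSubspace",
    "sample_subspace",
    "surface_area",
    "compare_conditions",
    "DEFAULT_BOX",
    "stress_conditions",
]


@dataclass(frozen=True)
class StressCondition:
    """A chronic-stress level, encoded as the CRH drive k_p1 in force."""

    label: str  # nominal | intermediate | high
    k_p1_value: float

    def apply(self, p: ModelParameters) -> ModelParameters:
        return p.replace(k_p1=self.k_p1_value)


def stress_conditions(
    p: ModelParameters,
    intermediate_factor: float = 1.5,
    high_factor: float = 2.0,
) -> tuple[StressCondition, StressCondition, StressCondition]:
    """Nominal / intermediate / high chronic-stress conditions.

    The chronic-stress drive multipliers are repository defaults: they are
    the largest sustained elevations of central drive for which the
    calibrated oscillator can still be compensated back to the homeostatic
    CORT rhythm by the three regulatory parameters (larger drives exceed
    the maximal light-enhanced CRH degradation and the hormone level grows
    without bound over most of the sampling box).
    """
    if not (1.0 < intermediate_factor < high_factor):
        raise ValueError("need 1 < intermediate_factor < high_factor")
    return (
        StressCondition("nominal", p.k_p1),
        StressCondition("intermediate", p.k_p1 * intermediate_factor),
        StressCondition("high", p.k_p1 * high_factor),
    )


@dataclass(frozen=True)
class SamplingBox:
    """Log-uniform sampling bounds for (K_p1, K_p2, k_p3)."""

    K_p1: tuple[float, float] = (0.10, 1.50)
    K_p2: tuple[float, float] = (0.40, 2.50)
    k_p3: tuple[float, float] = (0.35, 1.60)

    def __post_init__(self) -> None:
        for name in ("K_p1", "K_p2", "k_p3"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log([self.K_p1[0], self.K_p2[0], self.k_p3[0]])
        hi = np.log([self.K_p1[1], self.K_p2[1], self.k_p3[1]])
        return lo, hi

    def contains(self, triple: np.ndarray) -> bool:
        lo, hi = self.log_bounds
        x = np.log(np.asarray(triple, dtype=float))
        return bool(np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12))


DEFAULT_BOX = SamplingBox()


@dataclass
class AcceptedSubspace:
    """Accepted (K_p1, K_p2, k_p3) triples for one stress condition.

    ``table`` holds every evaluated sample (triple, fitted cosinor, accepted
    flag, convergence flag); ``triples`` is the accepted subset in draw
    order with duplicates removed.
    """

    condition: StressCondition
    triples: np.ndarray  # (n_accepted, 3)
    fits: list[CosinorFit]
    seed: int
    box: SamplingBox
    target: CalibrationTarget
    table: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def means(self) -> dict[str, float]:
        if len(self) == 0:
            return {"K_p1": np.nan, "K_p2": np.nan, "k_p3": np.nan}
        return {
            "K_p1": float(self.triples[:, 0].mean()),
            "K_p2": float(self.triples[:, 1].mean()),
            "k_p3": float(self.triples[:, 2].mean()),
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _draw_triples(box: SamplingBox, n: int, seed: int, sampler: str) -> np.ndarray:
    lo, hi = box.log_bounds
    if n == 0:
        return np.empty((0, 3))
    if sampler == "sobol":
        # draw a full power-of-two block (balance property), keep the first n
        m = int(np.ceil(np.log2(max(n, 2))))
        u = qmc.Sobol(d=3, scramble=True, seed=seed).random_base2(m)[:n]
    elif sampler == "uniform":
        u = np.random.default_rng(seed).random((n, 3))
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    return np.exp(lo + u * (hi - lo))


def sample_subspace(
    condition: StressCondition,
    target: CalibrationTarget,
    base_params: ModelParameters,
    schedule: LightSchedule | None = None,
    box: SamplingBox = DEFAULT_BOX,
    n_samples: int = 2000,
    seed: int = 0,
    sampler: str = "sobol",
    transient_days: int = 20,
    tol: float = 1e-3,
    max_days: int = 30,
    warm_start: bool = True,
) -> AcceptedSubspace:
    """Draw triples, simulate each to its entrained cycle, retain passers.

    Deterministic for a given seed and configuration.  ``warm_start``
    initializes every candidate from the converged state of the condition's
    base parameter set (computed once) instead of cold hormonal levels; the
    per-candidate convergence criterion is still enforced, so this is a
    speed optimization only.

    Returns an :class:`AcceptedSubspace`; if no triple passes, an
    :class:`EmptySubspaceWarning` is issued carrying the nearest misses.
    """
    schedule = schedule or LightSchedule()
    p_cond = condition.apply(base_params)
    triples = _draw_triples(box, n_samples, seed, sampler)

    y0 = default_initial_state()
    if warm_start:
        try:
            warm = integrate(
                p_cond, schedule, 0.0, transient_days * schedule.period, output_dt=None
            )
            if np.all(np.isfinite(warm.final_state)):
                y0 = warm.final_state
        except NonConvergence:
            pass

    rows = []
    accepted: list[np.ndarray] = []
    fits: list[CosinorFit] = []
    miss_scores: list[tuple[float, np.ndarray]] = []
    for triple in triples:
        p = p_cond.with_triple(*triple)
        row = {
            "K_p1": triple[0],
            "K_p2": triple[1],
            "k_p3": triple[2],
            "mesor": np.nan,
            "amplitude": np.nan,
            "acrophase": np.nan,
            "accepted": False,
            "converged": False,
        }
        try:
            cyc = integrate_to_limit_cycle(
                p,
                schedule,
                transient_days=transient_days,
                tol=tol,
                max_days=max_days,
                y0=y0,
            )
            fit = fit_cosinor(cyc.times, cyc.cort, period=schedule.period)
        except NonConvergence:
            rows.append(row)
            continue
        row.update(
            mesor=fit.mesor,
            amplitude=fit.amplitude,
            acrophase=fit.acrophase,
            converged=True,
        )
        ok = passes_calibration(fit, target)
        row["accepted"] = ok
        rows.append(row)
        if ok:
            accepted.append(triple)
            fits.append(fit)
        else:
            t = target.target
            from .cosinor import circular_distance

            score = max(
                abs(fit.mesor - t.mesor) / target.sd_mesor,
                abs(fit.amplitude - t.amplitude) / target.sd_amplitude,
                circular_distance(fit.acrophase, t.acrophase, t.period)
                / target.sd_acrophase,
            )
            miss_scores.append((score, triple))

    table = pd.DataFrame(
        rows,
        columns=[
            "K_p1",
            "K_p2",
            "k_p3",
            "mesor",
            "amplitude",
            "acrophase",
            "accepted",
            "converged",
        ],
    )
    tr = np.array(accepted) if accepted else np.empty((0, 3))
    if len(tr):
        # deduplicate, preserving draw order
        _, first = np.unique(tr, axis=0, return_index=True)
        keep = np.sort(first)
        tr = tr[keep]
        fits = [fits[i] for i in keep]
    sub = AcceptedSubspace(
        condition=condition,
        triples=tr,
        fits=fits,
        seed=seed,
        box=box,
        target=target,
        table=table,
    )
    if len(tr) == 0:
        miss_scores.sort(key=lambda s: s[0])
        nearest = [(float(s), t.tolist()) for s, t in miss_scores[:5]]
        warnings.warn(
            f"no accepted triples for condition {condition.label!r}; "
            f"nearest misses (max normalized deviation, triple): {nearest}",
            EmptySubspaceWarning,
            stacklevel=2,
        )
    return sub


# --- surface-area estimation ----------------------------------------------


def _circumradius(pts: np.ndarray) -> float:
    a = np.linalg.norm(pts[1] - pts[0])
    b = np.linalg.norm(pts[2] - pts[1])
    c = np.linalg.norm(pts[0] - pts[2])
    area2 = abs(
        (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1])
        - (pts[2][0] - pts[0][0]) * (pts[1][1] - pts[0][1])
    )
    if area2 == 0:
        return np.inf
    return a * b * c / (2.0 * area2)


def surface_area(
    points: "AcceptedSubspace | np.ndarray",
    alpha: float | None = None,
    normalize: str = "none",
) -> float:
    """Area of the accepted 2-manifold.

    Triangulates the accepted points in the (K_p1, K_p2) plane, discards
    Delaunay triangles whose circumradius exceeds ``alpha`` (default 2x the
    median nearest-neighbor spacing — an alpha-shape restriction preventing
    convex-hull overestimation of non-convex regions), lifts the surviving
    triangles to 3D via each point's k_p3, and sums their areas.

    ``normalize="none"`` works in raw parameter coordinates (area in the
    model's concentration units squared).  ``normalize="log"`` takes the
    natural log of all three coordinates first, giving a dimensionless
    relative-variability area: appropriate when the parameters are sampled
    log-uniformly and the accepted clouds are strongly anisotropic (a
    chronically stressed subspace can be orders of magnitude narrower in
    K_p1 than in K_p2, which starves a raw-coordinate alpha shape).
    """
    pts = points.triples if isinstance(points, AcceptedSubspace) else np.asarray(points)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometry("need at least 3 (K_p1, K_p2, k_p3) points")
    if normalize == "log":
        if np.any(pts <= 0):
            raise DegenerateGeometry("log normalization needs positive coordinates")
        pts = np.log(pts)
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    xy = pts[:, :2]
    if np.linalg.matrix_rank(xy - xy[0]) < 2:
        raise DegenerateGeometry("points are collinear in the (K_p1, K_p2) plane")
    if alpha is None:
        d, _ = cKDTree(xy).query(xy, k=2)
        alpha = 2.0 * float(np.median(d[:, 1]))
        if alpha <= 0:
            raise DegenerateGeometry("duplicate points give zero spacing")
    try:
        tri = Delaunay(xy)
    except Exception as exc:  # qhull degeneracies
        raise DegenerateGeometry(f"triangulation failed: {exc}") from exc
    total = 0.0
    for simplex in tri.simplices:
        flat = xy[simplex]
        if _circumradius(flat) > alpha:
            continue
        p3 = pts[simplex]
        total += 0.5 * float(
            np.linalg.norm(np.cross(p3[1] - p3[0], p3[2] - p3[0]))
        )
    return total


def compare_conditions(
    nominal: AcceptedSubspace,
    intermediate: AcceptedSubspace,
    high: AcceptedSubspace,
) -> dict:
    """Per-condition summaries and the ordered qualitative findings.

    Reports, for each condition, the accepted-triple means and ranges of
    the three regulatory parameters and the subspace area, plus booleans
    for the expected allostatic trends: mean K_p1 decreases with stress
    (stronger hypothalamic feedback), mean k_p3 increases (higher adrenal
    sensitivity), mean K_p2 increases (slightly weaker pituitary feedback)
    and subspace area decreases (loss of regulatory flexibility).
    """
    subs = {"nominal": nominal, "intermediate": intermediate, "high": high}
    out: dict = {"conditions": {}}
    for label, sub in subs.items():
        if len(sub) == 0:
            raise ValueError(f"condition {label!r} has an empty accepted set")
        entry = {
            "n_accepted": len(sub),
            "k_p1_drive": sub.condition.k_p1_value,
            "means": sub.means,
            "ranges": {
                k: (float(sub.triples[:, i].min()), float(sub.triples[:, i].max()))
                for i, k in enumerate(("K_p1", "K_p2", "k_p3"))
            },
        }
        for key, mode in (("area", "none"), ("area_log", "log")):
            try:
                entry[key] = surface_area(sub, normalize=mode)
            except DegenerateGeometry:
                entry[key] = np.nan
        out["conditions"][label] = entry

    m = {k: out["conditions"][k]["means"] for k in subs}
    # trend comparisons use the log-coordinate area: robust to the extreme
    # K_p1 narrowing of the stressed subspaces
    a = {k: out["conditions"][k]["area_log"] for k in subs}
    out["trends"] = {
        "mean_K_p1_decreases": m["nominal"]["K_p1"]
        > m["intermediate"]["K_p1"]
        > m["high"]["K_p1"],
        "mean_k_p3_increases": m["nominal"]["k_p3"]
        < m["intermediate"]["k_p3"]
        < m["high"]["k_p3"],
        "mean_K_p2_increases": m["nominal"]["K_p2"] < m["high"]["K_p2"],
        "area_decreases": a["nominal"] > a["intermediate"] > a["high"],
    }
    out["areas"] = a
    return out
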