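"""Monte-Carlo mixing-polygon validation of a mixing-model design.

A mass-balance mixing model can only explain a consumer whose isotope
value lies inside the polygon spanned by the (TDF-corrected) sources.
Because source positions are uncertain, the polygon itself is random:
each iteration draws every source position from
Normal(mu + lambda, sqrt(sigma^2 + tau^2)) per isotope, builds the
convex hull, and tests every consumer.  A consumer's inside-probability
is the fraction of simulated polygons covering it; the model design is
accepted when every consumer lies inside the 95% mixing region, i.e.
has inside-probability >= 0.05.  The probability surface on a grid
supports the conventional 10%-step contour plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietmix.mixing_model import DEFAULT_SEED, MixingData

_TOL = 1e-12


@dataclass
class PolygonSimConfig:
    n_iter: int = 1500
    seed: int = DEFAULT_SEED
    inclusion_threshold: float = 0.05
    use_sem: bool = False  # draw vertices from standard errors instead of sds
    source_ns: np.ndarray | None = None  # per-source n, required when use_sem
    grid_resolution: int = 200

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 < self.inclusion_threshold < 1.0:
            raise ValueError("inclusion_threshold must be in (0, 1)")


@dataclass
class PolygonResult:
    probabilities: pd.DataFrame  # sample_id, probability, passed
    threshold: float
    surface: np.ndarray | None = None  # grid of inside-probabilities
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    mean_vertices: np.ndarray | None = field(default=None, repr=False)

    @property
    def overall_pass(self) -> bool:
        return bool(self.probabilities["passed"].all())


def corrected_source_draw(data: MixingData, rng: np.random.Generator, scale: np.ndarray | None = None) -> np.ndarray:
    """One random position per source in isotope space (K x J).

    Positions are Normal(mu + lambda, sqrt(sigma^2 + tau^2)), independent
    across sources and isotopes; ``scale`` overrides the sd matrix.
    """
    sd = np.sqrt(data.corrected_vars) if scale is None else scale
    return data.corrected_means + sd * rng.standard_normal(data.corrected_means.shape)


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull by Andrew's monotone chain; counter-clockwise vertices.

    Collinear boundary points are dropped.  Degenerate inputs return a
    single point (all coincident) or the two extreme points (collinear).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(pts) == 1:
        return pts
    # np.unique sorts lexicographically (x, then y)
    if len(pts) == 2:
        return pts

    def half(iterable):
        chain: list[np.ndarray] = []
        for p in iterable:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all points collinear
        return np.array([pts[0], pts[-1]])
    return np.array(hull)


def point_in_polygon(point: np.ndarray, polygon: np.ndarray, tol: float = _TOL) -> bool:
    """Inside-or-on-boundary test against a CCW convex polygon."""
    return bool(points_in_polygon(np.atleast_2d(point), polygon, tol)[0])


def points_in_polygon(points: np.ndarray, polygon: np.ndarray, tol: float = _TOL) -> np.ndarray:
    """Vectorised inside test; handles degenerate 1- and 2-vertex hulls."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.atleast_2d(np.asarray(polygon, dtype=float))
    if len(poly) == 1:
        return np.linalg.norm(pts - poly[0], axis=1) <= tol
    if len(poly) == 2:
        a, b = poly
        ab = b - a
        denom = ab @ ab
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        nearest = a + t[:, None] * ab
        return np.linalg.norm(pts - nearest, axis=1) <= tol
    inside = np.ones(len(pts), dtype=bool)
    for i in range(len(poly)):
        a = poly[i]
        b = poly[(i + 1) % len(poly)]
        cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        inside &= cross >= -tol
    return inside


def consumer_probabilities(
    consumers: pd.DataFrame | np.ndarray,
    data: MixingData,
    config: PolygonSimConfig | None = None,
    compute_surface: bool = False,
) -> PolygonResult:
    """Inside-hull probability for every consumer.

    ``consumers`` is an n x 2 array or a frame with the isotope columns
    named in ``data.isotope_names`` (and optionally ``sample_id``).
    """
    config = config or PolygonSimConfig()
    if isinstance(consumers, pd.DataFrame):
        ids = (
            consumers["sample_id"].to_list()
            if "sample_id" in consumers.columns
            else list(range(len(consumers)))
        )
        xy = consumers[list(data.isotope_names)].to_numpy(dtype=float)
    else:
        xy = np.atleast_2d(np.asarray(consumers, dtype=float))
        ids = list(range(len(xy)))
    rng = np.random.default_rng(config.seed)

    scale = np.sqrt(data.corrected_vars)
    if config.use_sem:
        ns = np.asarray(config.source_ns, dtype=float)
        if ns.shape != (data.n_sources,):
            raise ValueError("use_sem requires per-source sample sizes")
        scale = scale / np.sqrt(ns)[:, None]

    grid_pts = gx = gy = None
    surface_counts = None
    if compute_surface:
        res = config.grid_resolution
        lo = np.minimum(xy.min(axis=0), data.corrected_means.min(axis=0)) - 1.0
        hi = np.maximum(xy.max(axis=0), data.corrected_means.max(axis=0)) + 1.0
        gx = np.linspace(lo[0], hi[0], res)
        gy = np.linspace(lo[1], hi[1], res)
        mx, my = np.meshgrid(gx, gy)
        grid_pts = np.column_stack([mx.ravel(), my.ravel()])
        surface_counts = np.zeros(len(grid_pts))

    counts = np.zeros(len(xy))
    for _ in range(config.n_iter):
        vertices = corrected_source_draw(data, rng, scale=scale)
        hull = convex_hull(vertices)
        counts += points_in_polygon(xy, hull)
        if surface_counts is not None:
            surface_counts += points_in_polygon(grid_pts, hull)

    probs = counts / config.n_iter
    table = pd.DataFrame(
        {
            "sample_id": ids,
            "probability": probs,
            "passed": probs >= config.inclusion_threshold,
        }
    )
    surface = (
        (surface_counts / config.n_iter).reshape(config.grid_resolution, config.grid_resolution)
        if surface_counts is not None
        else None
    )
    return PolygonResult(
        probabilities=table,
        threshold=config.inclusion_threshold,
        surface=surface,
        grid_x=gx,
        grid_y=gy,
        mean_vertices=data.corrected_means,
    )


def validate_design(result: PolygonResult) -> dict:
    """Overall accept/reject report for the mixing-model design.

    The design passes when every consumer's inside-probability reaches
    the inclusion threshold; an empty consumer set passes vacuously
    (with a warning flag in the report).
    """
    failing = result.probabilities.loc[~result.probabilities["passed"], "sample_id"].to_list()
    empty = result.probabilities.empty
    return {
        "passed": result.overall_pass,
        "threshold": result.threshold,
        "n_consumers": len(result.probabilities),
        "failing_consumers": failing,
        "vacuous": empty,
    }
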