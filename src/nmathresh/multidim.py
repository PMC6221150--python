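"""Simultaneous bias adjustment in several data points.

Allowing r components of the adjustment vector beta to be non-zero turns
each threshold point into a hyperplane beta' w_a = 1, where the i-th
component of w_a is 1/u_{a,i} on the adjusted index set and 0 elsewhere
(1/inf = 0).  In two dimensions the hyperplanes are lines

    beta_{m2} = u_{a,m2} - (u_{a,m2} / u_{a,m1}) beta_{m1},

whose axis intercepts are the one-dimensional thresholds.  Their
intersection about the origin is the convex decision-invariant region; the
point of each hyperplane closest to the origin, beta_min = w / ||w||^2, is
the smallest overall simultaneous adjustment that makes treatment a
optimal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

from .thresholds import SolutionSet

__all__ = [
    "ThresholdLine",
    "ThresholdHyperplane",
    "InvariantRegion2D",
    "threshold_lines_2d",
    "invariant_region_2d",
    "beta_min",
    "common_bias_region_2d",
]

logger = logging.getLogger(__name__)

#: Half-width of the bounding box used to clip open invariant regions,
#: as a multiple of the largest finite |u| involved.
_BOX_FACTOR = 10.0


@dataclass
class ThresholdLine:
    """Line beta' w = 1 in the (beta_m1, beta_m2) plane for new optimum a."""

    a: int
    w: np.ndarray  # length 2; components are 1/u (0 when u infinite)

    @property
    def intercepts(self) -> tuple[float, float]:
        """Axis crossings: the 1-D thresholds u_{a,m1}, u_{a,m2}."""
        return tuple(1.0 / wi if wi != 0 else math.inf for wi in self.w)


@dataclass
class ThresholdHyperplane:
    """Hyperplane beta' w = 1 over the full data space for new optimum a."""

    a: int
    w: np.ndarray  # length N, zero off the adjusted index set

    @property
    def beta_min(self) -> np.ndarray:
        """Closest point of the plane to the origin, w / ||w||^2."""
        n2 = float(self.w @ self.w)
        return self.w / n2

    @property
    def distance(self) -> float:
        return 1.0 / float(np.linalg.norm(self.w))


@dataclass
class InvariantRegion2D:
    """Convex invariant polygon (clipped to a large box when open)."""

    indices: tuple
    vertices: np.ndarray                 # CCW boundary vertices
    segments: list[tuple[np.ndarray, np.ndarray, int | None]]
    closed: bool
    lines: list[ThresholdLine] = field(default_factory=list)

    def contains(self, point) -> bool:
        """True when the adjustment leaves the optimal treatment unchanged."""
        p = np.asarray(point, float)
        return all(float(p @ ln.w) < 1.0 for ln in self.lines)


def _inverse(u: float) -> float:
    if math.isinf(u):
        return 0.0
    if u == 0.0:
        return math.inf  # degenerate: the origin already lies on a threshold
    return 1.0 / u


def threshold_lines_2d(
    solutions_m1: SolutionSet, solutions_m2: SolutionSet
) -> list[ThresholdLine]:
    """One threshold line per alternative reachable through either datum."""
    if solutions_m1.kstar != solutions_m2.kstar:
        raise ValueError(
            "solution sets disagree on the base optimum "
            f"({solutions_m1.kstar} vs {solutions_m2.kstar})"
        )
    lines = []
    for a in sorted(set(solutions_m1.u) & set(solutions_m2.u)):
        w = np.array([_inverse(solutions_m1.u[a]), _inverse(solutions_m2.u[a])])
        if not w.any():
            logger.info(
                "treatment %d unreachable through the chosen data; line dropped", a
            )
            continue
        lines.append(ThresholdLine(a=a, w=w))
    return lines


def invariant_region_2d(
    lines: list[ThresholdLine], indices: tuple = (0, 1)
) -> InvariantRegion2D:
    """Intersection of the origin-side half-planes {beta' w <= 1}.

    The region is convex; when some direction is unbounded (no threshold
    line that way) it is clipped to a large box and flagged open, with the
    box-edge segments labelled None (rays to infinity).
    """
    usable = []
    for ln in lines:
        if np.linalg.norm(ln.w) == 0:
            raise ValueError("degenerate line with w = 0")
        if not np.all(np.isfinite(ln.w)):
            # a 1-D threshold of exactly 0: origin sits on this line
            warnings.warn(
                f"origin lies on the threshold line for treatment {ln.a} "
                "(degenerate decision)",
                UserWarning,
                stacklevel=2,
            )
            continue
        usable.append(ln)
    lines = usable
    finite_u = [
        abs(1.0 / wi) for ln in lines for wi in ln.w if wi != 0
    ]
    extent = _BOX_FACTOR * max(finite_u) if finite_u else 1.0
    region = box(-extent, -extent, extent, extent)
    for ln in lines:
        region = region.intersection(_half_plane(ln.w, extent))
        if region.is_empty:
            break
    closed = (not region.is_empty) and _strictly_inside_box(region, extent)
    segments: list = []
    verts = np.zeros((0, 2))
    if not region.is_empty:
        region = orient(region, sign=1.0)
        coords = np.asarray(region.exterior.coords)
        verts = coords[:-1]
        for p1, p2 in zip(coords[:-1], coords[1:]):
            mid = 0.5 * (p1 + p2)
            label = None
            for ln in lines:
                if abs(float(mid @ ln.w) - 1.0) < 1e-9 * max(1.0, extent):
                    label = ln.a
                    break
            segments.append((p1, p2, label))
    return InvariantRegion2D(
        indices=tuple(indices), vertices=verts, segments=segments,
        closed=closed, lines=list(lines),
    )


def _half_plane(w: np.ndarray, extent: float) -> Polygon:
    """Polygon for {beta : beta' w <= 1} clipped well beyond the box."""
    nw = float(np.linalg.norm(w))
    p0 = w / nw**2                       # foot of the perpendicular
    t = np.array([-w[1], w[0]]) / nw     # direction along the line
    wh = w / nw
    big = 4.0 * extent
    pts = [
        p0 + big * t,
        p0 - big * t,
        p0 - big * t - 2.0 * big * wh,
        p0 + big * t - 2.0 * big * wh,
    ]
    return Polygon(pts)


def _strictly_inside_box(region, extent: float) -> bool:
    minx, miny, maxx, maxy = region.bounds
    eps = 1e-9 * extent
    return (
        minx > -extent + eps and miny > -extent + eps
        and maxx < extent - eps and maxy < extent - eps
    )


def beta_min(
    solutions: list[SolutionSet] | SolutionSet, index_set=None
) -> list[ThresholdHyperplane]:
    """Minimal simultaneous adjustment vectors, one hyperplane per reachable a.

    ``solutions`` holds one SolutionSet per adjusted datum (all sharing k*);
    ``index_set`` gives each datum's position in the full data vector
    (defaults to the SolutionSet.m values).  Results are sorted by the norm
    of beta_min ascending — the easiest decision changes first.
    """
    if isinstance(solutions, SolutionSet):
        solutions = [solutions]
    if not solutions:
        raise ValueError("need at least one solution set")
    kstar = solutions[0].kstar
    if any(s.kstar != kstar for s in solutions):
        raise ValueError("solution sets disagree on the base optimum")
    if index_set is None:
        index_set = [s.m if isinstance(s.m, int) else min(s.m) for s in solutions]
    n = max(index_set) + 1
    planes = []
    for a in sorted(set.intersection(*[set(s.u) for s in solutions])):
        w = np.zeros(n)
        for s, idx in zip(solutions, index_set):
            w[idx] = _inverse(s.u[a])
        if not w.any():
            continue
        planes.append(ThresholdHyperplane(a=a, w=w))
    planes.sort(key=lambda p: p.distance)
    return planes


def common_bias_region_2d(
    set_m1: SolutionSet, set_m2: SolutionSet
) -> InvariantRegion2D:
    """2-D invariant region for two *common* biases on disjoint index sets.

    Each axis carries one shared adjustment applied to every datum in the
    corresponding set; the solution sets come from
    :func:`~nmathresh.thresholds.common_bias_solution_set`.
    """
    m1 = set_m1.m if isinstance(set_m1.m, frozenset) else frozenset([set_m1.m])
    m2 = set_m2.m if isinstance(set_m2.m, frozenset) else frozenset([set_m2.m])
    if m1 & m2:
        raise ValueError(f"index sets overlap: {sorted(m1 & m2)}")
    lines = threshold_lines_2d(set_m1, set_m2)
    return invariant_region_2d(lines, indices=(tuple(sorted(m1)), tuple(sorted(m2))))
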