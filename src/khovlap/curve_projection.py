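"""Planar diagrams from closed 3D curves.

A closed space curve (a parametric sampler, a polyline from a CSV file, or
a seeded random trigonometric-polynomial curve) is projected onto a
coordinate plane; transverse self-intersections of the projected closed
polyline become crossings, with the strand of greater depth taken to pass
over.  Edges are then numbered along the curve and each crossing emitted in
PD form, yielding a diagram the rest of the package can consume.  This is
the entry point for knot data analysis of curves such as circularized
biomolecular backbones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .link_diagram import Crossing, LinkDiagram

__all__ = [
    "Curve3D",
    "ProjectionSpec",
    "PlanarCrossing",
    "NonGenericProjectionError",
    "sample_parametric",
    "trefoil_curve",
    "random_fourier_knot",
    "detect_crossings",
    "build_pd",
    "diagram_from_curve",
    "read_polyline_csv",
]

# genericity tolerances, applied after normalizing the curve to unit diameter
ANGLE_TOL = 1e-3  # radians: minimum intersection angle
SEPARATION_TOL = 1e-6  # minimum in-plane distance between distinct crossings
DEPTH_TOL = 1e-9  # minimum depth difference at a crossing

_AXES = {"x": 0, "y": 1, "z": 2}


class NonGenericProjectionError(ValueError):
    """The projection violates a genericity tolerance; resample or perturb."""


@dataclass
class Curve3D:
    """A closed polyline in R^3 (the closing edge last-to-first is implicit)."""

    points: np.ndarray  # (n, 3)
    source: str = "polyline"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 8:
            raise ValueError("a closed curve needs at least 8 points")
        deltas = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        if np.any(np.all(deltas == 0.0, axis=1)):
            raise ValueError("consecutive points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ProjectionSpec:
    """Which two coordinates span the diagram plane; the third is depth.

    The strand with the greater depth coordinate passes over.  The in-plane
    frame (a, b) is ordered so that (a, b, depth) is a left-handed triple;
    this single orientation convention makes the diagrams of all three
    projections of one curve represent the same knot, and reproduces the
    standard 3-crossing right-handed trefoil from the x-z projection of the
    classic trefoil parametrization.
    """

    plane: str = "xz"  # two of x, y, z

    def __post_init__(self) -> None:
        if sorted(self.plane) not in (["x", "y"], ["x", "z"], ["y", "z"]):
            raise ValueError(f"plane must name two distinct axes, got {self.plane!r}")

    @property
    def plane_axes(self) -> tuple[int, int]:
        # left-handed with the depth axis: xy -> (y, x), xz -> (x, z), yz -> (z, y)
        key = "".join(sorted(self.plane))
        return {"xy": (1, 0), "xz": (0, 2), "yz": (2, 1)}[key]

    @property
    def depth_axis(self) -> int:
        (rem,) = set(range(3)) - set(self.plane_axes)
        return rem


@dataclass(frozen=True)
class PlanarCrossing:
    """One transverse self-intersection of the projected curve.

    ``t_under``/``t_over`` are fractional positions along the closed curve
    (segment index plus fraction), and the direction vectors are the local
    in-plane tangents of the two strands.
    """

    point: tuple[float, float]
    t_under: float
    t_over: float
    dir_under: tuple[float, float]
    dir_over: tuple[float, float]


# ----------------------------------------------------------------------
# curve constructors


def sample_parametric(
    fn: Callable[[np.ndarray], tuple], n_samples: int = 4096,
    u_range: tuple[float, float] = (0.0, 2.0 * np.pi),
) -> Curve3D:
    """Sample a closed parametric curve uniformly (endpoint excluded)."""
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    u = np.linspace(u_range[0], u_range[1], n_samples, endpoint=False)
    x, y, z = fn(u)
    pts = np.column_stack([np.broadcast_to(x, u.shape),
                           np.broadcast_to(y, u.shape),
                           np.broadcast_to(z, u.shape)])
    return Curve3D(points=pts, source="parametric")


def trefoil_curve(n_samples: int = 4096) -> Curve3D:
    """The closed trefoil parametrization
    (x,y,z) = (sin u + 2 sin 2u, sin 3u, 2 cos 2u - cos u), u in [0, 2pi]."""
    return sample_parametric(
        lambda u: (np.sin(u) + 2.0 * np.sin(2.0 * u), np.sin(3.0 * u),
                   2.0 * np.cos(2.0 * u) - np.cos(u)),
        n_samples=n_samples,
    )


def random_fourier_knot(seed: int, n_modes: int = 6, n_samples: int = 512) -> Curve3D:
    """A seeded random closed curve with trigonometric-polynomial coordinates.

    Each coordinate is sum_m (a_m cos(m u) + b_m sin(m u)) with coefficients
    drawn from a seeded normal generator and decaying like 1/m.  With the
    default six modes, generic projections yield diagrams spread over roughly
    0-10 crossings: mostly unknots and small knots, with occasional larger
    diagrams.
    """
    if n_modes < 2:
        raise ValueError("n_modes must be at least 2")
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    coords = []
    for _ in range(3):
        acc = np.zeros_like(u)
        for m in range(1, n_modes + 1):
            a, b = rng.normal(size=2) / m
            acc += a * np.cos(m * u) + b * np.sin(m * u)
        coords.append(acc)
    return Curve3D(points=np.column_stack(coords), source="parametric")


def read_polyline_csv(path_or_buffer) -> Curve3D:
    """Read a closed polyline from CSV with header ``x,y,z``."""
    if isinstance(path_or_buffer, (str, bytes)):
        with open(path_or_buffer) as fh:
            text = fh.read()
    elif isinstance(path_or_buffer, io.IOBase):
        text = path_or_buffer.read()
    else:
        text = str(path_or_buffer)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header != ["x", "y", "z"]:
        raise ValueError("polyline CSV must have header x,y,z")
    pts = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    return Curve3D(points=pts, source="polyline")


# ----------------------------------------------------------------------
# crossing detection


def _segment_intersections(P: np.ndarray) -> list[tuple[int, int, float, float]]:
    """All transverse intersections between non-adjacent segments of the
    closed 2D polyline P, as (segment i, segment j, fraction on i, fraction on j)."""
    n = len(P)
    A = P
    B = np.roll(P, -1, axis=0)
    d = B - A
    out: list[tuple[int, int, float, float]] = []
    # bounding-box prefilter, vectorized per segment
    lo = np.minimum(A, B)
    hi = np.maximum(A, B)
    for i in range(n - 2):
        # candidate j > i+1, excluding the closure adjacency (i=0, j=n-1)
        j_start = i + 2
        j_end = n - 1 if i == 0 else n
        js = np.arange(j_start, j_end)
        if len(js) == 0:
            continue
        mask = (
            (lo[js, 0] <= hi[i, 0]) & (hi[js, 0] >= lo[i, 0])
            & (lo[js, 1] <= hi[i, 1]) & (hi[js, 1] >= lo[i, 1])
        )
        js = js[mask]
        if len(js) == 0:
            continue
        r = d[i]
        diff = A[js] - A[i]
        cross_rs = r[0] * d[js, 1] - r[1] * d[js, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (diff[:, 0] * d[js, 1] - diff[:, 1] * d[js, 0]) / cross_rs
            s = (diff[:, 0] * r[1] - diff[:, 1] * r[0]) / cross_rs
        ok = (cross_rs != 0) & (t > 0) & (t < 1) & (s > 0) & (s < 1)
        for jj, tt, ss in zip(js[ok], t[ok], s[ok]):
            out.append((i, int(jj), float(tt), float(ss)))
    return out


def detect_crossings(curve: Curve3D, spec: ProjectionSpec) -> list[PlanarCrossing]:
    """Transverse self-intersections of the projected closed polyline.

    Raises :class:`NonGenericProjectionError` for near-tangential
    intersections, near-coincident crossing points, or near-equal depths.
    """
    pts = curve.points
    # normalize to unit diameter so the tolerances are scale-free
    span = np.ptp(pts, axis=0).max()
    if span <= 0:
        raise NonGenericProjectionError("degenerate curve with zero extent")
    pts = pts / span
    ax, ay = spec.plane_axes
    az = spec.depth_axis
    P = pts[:, [ax, ay]]
    depth = pts[:, az]
    n = len(P)
    d2 = np.roll(P, -1, axis=0) - P

    raw = _segment_intersections(P)
    crossings: list[PlanarCrossing] = []
    for i, j, t, s in raw:
        di, dj = d2[i], d2[j]
        angle = np.arctan2(abs(di[0] * dj[1] - di[1] * dj[0]), abs(di @ dj))
        if angle < ANGLE_TOL:
            raise NonGenericProjectionError(
                f"near-tangential intersection of segments {i} and {j} "
                f"(angle {angle:.2e} rad); resample or perturb the projection"
            )
        point = P[i] + t * di
        depth_i = depth[i] + t * (depth[(i + 1) % n] - depth[i])
        depth_j = depth[j] + s * (depth[(j + 1) % n] - depth[j])
        if abs(depth_i - depth_j) < DEPTH_TOL:
            raise NonGenericProjectionError(
                f"equal depths at intersection of segments {i} and {j}; "
                "perturb the projection"
            )
        ti, tj = i + t, j + s
        if depth_i > depth_j:
            t_over, t_under = ti, tj
            dir_over, dir_under = di, dj
        else:
            t_over, t_under = tj, ti
            dir_over, dir_under = dj, di
        crossings.append(
            PlanarCrossing(
                point=(float(point[0]), float(point[1])),
                t_under=t_under,
                t_over=t_over,
                dir_under=(float(dir_under[0]), float(dir_under[1])),
                dir_over=(float(dir_over[0]), float(dir_over[1])),
            )
        )
    # triple points / coincident crossings
    for a in range(len(crossings)):
        pa = np.array(crossings[a].point)
        for b in range(a + 1, len(crossings)):
            pb = np.array(crossings[b].point)
            if np.hypot(*(pa - pb)) < SEPARATION_TOL:
                raise NonGenericProjectionError(
                    f"two crossings closer than {SEPARATION_TOL} (near triple point)"
                )
    return crossings


# ----------------------------------------------------------------------
# PD construction


def build_pd(curve: Curve3D, crossings: Sequence[PlanarCrossing]) -> LinkDiagram:
    """Number the edges along the curve and emit each crossing as X(i,j,k,l).

    The under-strand enters at i; j, k, l follow counterclockwise in the
    projection plane.  Edge 1 starts just after the first crossing pass
    encountered from the curve's start point.
    """
    if not crossings:
        return LinkDiagram(crossings=[])
    # one pass per strand per crossing, ordered along the curve
    passes = []  # (position, crossing index, is_under)
    for ci, c in enumerate(crossings):
        passes.append((c.t_under, ci, True))
        passes.append((c.t_over, ci, False))
    passes.sort()
    n2 = len(passes)
    # edge label between consecutive passes: edge e runs from pass e-1 to pass e
    # (1-based, wrapping), so pass p has incoming edge p+1? -- we assign:
    # incoming edge of pass index p (0-based) is p (1-based label p, with the
    # edge before pass 0 labeled n2), outgoing is p+1.
    incoming = {}
    outgoing = {}
    for p in range(n2):
        incoming[p] = p if p > 0 else n2
        outgoing[p] = p + 1
    by_crossing: dict[int, dict[str, int]] = {}
    for p, (pos, ci, is_under) in enumerate(passes):
        slot = by_crossing.setdefault(ci, {})
        key = "under" if is_under else "over"
        slot[key + "_in"] = incoming[p]
        slot[key + "_out"] = outgoing[p] if outgoing[p] <= n2 else outgoing[p] - n2
    pd: list[Crossing] = []
    for ci, c in enumerate(crossings):
        ports = by_crossing[ci]
        du = np.array(c.dir_under)
        do = np.array(c.dir_over)
        cross = du[0] * do[1] - du[1] * do[0]
        i = ports["under_in"]
        k = ports["under_out"]
        if cross > 0:
            # over-strand direction is counterclockwise from the under-strand:
            # counterclockwise from the incoming under edge sits the incoming
            # over edge, making the crossing positive
            j, l = ports["over_in"], ports["over_out"]
        else:
            j, l = ports["over_out"], ports["over_in"]
        pd.append(Crossing(edges=(i, j, k, l), index=ci))
    return LinkDiagram(crossings=pd)


def diagram_from_curve(curve: Curve3D, spec: ProjectionSpec) -> LinkDiagram:
    """Full pipeline: project, detect crossings, and build a validated PD."""
    return build_pd(curve, detect_crossings(curve, spec))
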