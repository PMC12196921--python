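"""Independent brute-force oracles used to check the fast implementations.

Deliberately naive: dense scans built on shapely geometry predicates and
plain-Python ECDF enumeration, sharing no code with the package's
vectorised routines.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Polygon


def chord_through_point_scan(vertices: np.ndarray, point, n_dirs: int = 3600
                             ) -> float:
    """Max through-point chord by dense angular scan (shapely boundary)."""
    poly = Polygon(vertices)
    boundary = poly.exterior
    p = np.asarray(point, dtype=float)
    span = 4.0 * max(poly.bounds[2] - poly.bounds[0],
                     poly.bounds[3] - poly.bounds[1])
    best = 0.0
    for theta in np.linspace(0.0, np.pi, n_dirs, endpoint=False):
        u = np.array([np.cos(theta), np.sin(theta)])
        line = LineString([p - span * u, p + span * u])
        inter = line.intersection(boundary)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        offs = []
        for g in geoms:
            coords = np.asarray(g.coords)
            offs.extend((coords - p) @ u)
        offs = np.asarray(offs)
        pos, neg = offs[offs > 0], offs[offs < 0]
        if len(pos) and len(neg):
            best = max(best, pos.max() - neg.min())
    return best


def width_perpendicular_scan(vertices: np.ndarray, axis_u,
                             n_stations: int = 2000) -> float:
    """Max perpendicular chord by dense station scan (shapely boundary)."""
    poly = Polygon(vertices)
    boundary = poly.exterior
    u = np.asarray(axis_u, dtype=float)
    u = u / np.hypot(*u)
    v = np.array([-u[1], u[0]])
    proj = vertices @ u
    span = 4.0 * max(poly.bounds[2] - poly.bounds[0],
                     poly.bounds[3] - poly.bounds[1])
    best = 0.0
    for t in np.linspace(proj.min(), proj.max(), n_stations + 2)[1:-1]:
        q = t * u
        line = LineString([q - span * v, q + span * v])
        inter = line.intersection(boundary)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        offs = []
        for g in geoms:
            coords = np.asarray(g.coords)
            offs.extend((coords - q) @ v)
        if len(offs) >= 2:
            best = max(best, max(offs) - min(offs))
    return best


def ks_d_enumerate(x, y) -> float:
    """Two-sample KS D by evaluating both ECDFs at every observed point."""
    x, y = list(x), list(y)
    best = 0.0
    for v in x + y:
        fx = sum(1 for xi in x if xi <= v) / len(x)
        fy = sum(1 for yi in y if yi <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


def random_star_polygon(rng: np.random.Generator, convex: bool = False,
                        n_vertices: int = 72) -> np.ndarray:
    """Random smooth simple polygon (star-shaped radial perturbation)."""
    if convex:
        pts = rng.normal(size=(40, 2)) * rng.uniform(5, 30, size=2)
        from scipy.spatial import ConvexHull
        hull = pts[ConvexHull(pts).vertices]
        # densify hull edges so the polygon has plenty of vertices
        out = []
        for i in range(len(hull)):
            a, b = hull[i], hull[(i + 1) % len(hull)]
            for f in np.linspace(0, 1, 6, endpoint=False):
                out.append(a + f * (b - a))
        return np.asarray(out)
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    base = rng.uniform(10, 30)
    r = np.full_like(phi, base)
    for k in range(2, 6):
        r += base * rng.uniform(0, 0.12) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.2 * base, None)
    stretch = rng.uniform(1.0, 2.0)
    return np.column_stack([stretch * r * np.cos(phi), r * np.sin(phi)])


def interior_point(vertices: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    """Random point strictly inside a polygon, away from the boundary."""
    poly = Polygon(vertices)
    shrunk = poly.buffer(-0.05 * np.sqrt(poly.area))
    if shrunk.is_empty:
        shrunk = poly
    xmin, ymin, xmax, ymax = shrunk.bounds
    from shapely.geometry import Point
    while True:
        p = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        if shrunk.contains(Point(p)):
            return p
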