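"""Quantitative granule morphometrics from 2D contours.

A starch granule is represented by its boundary polygon (in µm) together
with the annotated hilum, the point of origin around which carbohydrate
lamellae are deposited.  Four quantities are measured per granule:

``max_length``
    the longest chord of the outline constrained to pass through the
    hilum (a caliper-style measurement, matching how granules are
    measured on screen);
``max_width``
    the longest chord perpendicular to the length axis (it need not pass
    through the hilum);
``eccentricity_ratio`` (ER)
    distance from the hilum to the proximal end of the length axis (the
    end nearer the hilum) divided by the maximum length.  By definition
    the proximal end is the nearer one, so ER lies in [0, 0.5]; 0 means
    the hilum sits on the granule edge, 0.5 dead centre;
``hilum_angle``
    the angle, with vertex at the hilum, subtended by the two endpoints
    of the maximum-width chord.  It is wide when the hilum sits close to
    the width chord and narrows as the hilum retreats toward an end of
    the granule.

All lengths are µm, all angles degrees, coordinates are continuous and
y-up.  The chord searches are dense angular / station scans refined by
golden-section iteration; the documented angular resolution is 0.05°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InvalidGranuleError

PointPair = tuple[tuple[float, float], tuple[float, float]]

_COARSE_DIRECTIONS = 720          # directions in [0, pi) for the length scan
_COARSE_STATIONS = 512            # stations along the axis for the width scan
_GOLDEN_TOL_RAD = np.deg2rad(0.01)  # final bracket width, well under 0.05 deg
_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GranuleContour:
    """Closed simple polygon outline (µm) with an annotated hilum point.

    ``hilum`` may be ``None`` for contours freshly extracted from masks;
    every measurement that needs the hilum raises until it is set.
    """

    vertices: np.ndarray
    hilum: Optional[tuple[float, float]] = None
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidGranuleError("vertices must be an (N, 2) array")
        # drop an explicit closing vertex
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 8:
            raise InvalidGranuleError(
                f"contour needs >= 8 vertices, got {len(v)}")
        self.vertices = v
        poly = _ShapelyPolygon(v)
        if not poly.is_valid or not poly.is_simple:
            raise InvalidGranuleError("contour polygon is not simple")
        if poly.area <= 1e-9:
            raise InvalidGranuleError("contour polygon has ~zero area")
        if self.hilum is not None:
            h = (float(self.hilum[0]), float(self.hilum[1]))
            if not poly.contains(_ShapelyPoint(h)):
                raise InvalidGranuleError(
                    f"hilum {h} is not strictly inside the contour")
            self.hilum = h

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def with_hilum(self, hilum: Sequence[float]) -> "GranuleContour":
        return GranuleContour(self.vertices.copy(),
                              (float(hilum[0]), float(hilum[1])), self.id)


@dataclass(frozen=True)
class GranuleMeasurement:
    """The four morphometrics of one granule plus the defining chords.

    ``length_axis`` is ordered proximal end (nearer the hilum) first.
    Records read from measurement tables carry no chords (``None``).
    """

    max_length: float
    max_width: float
    eccentricity_ratio: float
    hilum_angle: float
    length_axis: Optional[PointPair] = None
    width_chord: Optional[PointPair] = None

    def __post_init__(self) -> None:
        if not (self.max_width > 0 and self.max_length > 0):
            raise InvalidGranuleError("lengths must be positive")
        if not (0.0 <= self.eccentricity_ratio <= 0.5 + 1e-9):
            raise InvalidGranuleError(
                f"eccentricity ratio {self.eccentricity_ratio} outside [0, 0.5]")
        if not (0.0 < self.hilum_angle <= 180.0 + 1e-9):
            raise InvalidGranuleError(
                f"hilum angle {self.hilum_angle} outside (0, 180]")


# ---------------------------------------------------------------------------
# vectorised line/polygon intersection core
# ---------------------------------------------------------------------------

def _edges(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    return a, b


def _line_crossings(vertices: np.ndarray, point: np.ndarray,
                    directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed offsets of boundary crossings for a fan of lines.

    For each unit direction ``u`` the line is ``point + t*u``; returns
    ``(t_min, t_max)`` per direction, the extreme crossings with the
    polygon boundary (NaN where fewer than two crossings exist).
    """
    a, b = _edges(vertices)
    d = b - a                      # (E, 2) edge vectors
    w = a - point                  # (E, 2)
    u = directions                 # (D, 2)
    # cross(u, d) per (D, E)
    cross_ud = u[:, None, 0] * d[None, :, 1] - u[:, None, 1] * d[None, :, 0]
    cross_wd = w[:, 0] * d[:, 1] - w[:, 1] * d[:, 0]          # (E,)
    cross_wu = (w[None, :, 0] * u[:, None, 1]
                - w[None, :, 1] * u[:, None, 0])              # (D, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_wd[None, :] / cross_ud
        s = cross_wu / cross_ud
    eps = 1e-12
    ok = (np.abs(cross_ud) > 1e-15) & (s >= -eps) & (s <= 1.0 + eps)
    t = np.where(ok, t, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        t_min = np.nanmin(t, axis=1)
        t_max = np.nanmax(t, axis=1)
    n_ok = ok.sum(axis=1)
    bad = n_ok < 2
    t_min = np.where(bad, np.nan, t_min)
    t_max = np.where(bad, np.nan, t_max)
    return t_min, t_max


def _chord_lengths(vertices: np.ndarray, point: np.ndarray,
                   thetas: np.ndarray) -> np.ndarray:
    """Through-point chord length at each direction angle (radians)."""
    u = np.column_stack([np.cos(thetas), np.sin(thetas)])
    t_min, t_max = _line_crossings(vertices, point, u)
    return t_max - t_min


def _golden_max(fun, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximiser on [lo, hi]; returns the argmax."""
    x1 = hi - _INV_PHI * (hi - lo)
    x2 = lo + _INV_PHI * (hi - lo)
    f1, f2 = fun(x1), fun(x2)
    while (hi - lo) > tol:
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _INV_PHI * (hi - lo)
            f2 = fun(x2)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _INV_PHI * (hi - lo)
            f1 = fun(x1)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def max_chord_through_point(
        contour: GranuleContour) -> tuple[float, PointPair]:
    """Maximum length of the granule measured through the hilum.

    Over all directions θ ∈ [0, π) the line through the hilum is
    intersected with the boundary; on each side of the hilum the farthest
    intersection is kept (so for strongly curved granules the chord may
    briefly leave the polygon, as a caliper measurement would).  Returns
    the maximal chord length and its endpoints, proximal end first.
    Ties between directions resolve to the smallest θ.
    """
    if contour.hilum is None:
        raise InvalidGranuleError("contour has no hilum annotation")
    v = contour.vertices
    h = np.asarray(contour.hilum, dtype=float)

    thetas = np.linspace(0.0, np.pi, _COARSE_DIRECTIONS, endpoint=False)
    lengths = _chord_lengths(v, h, thetas)
    if np.all(np.isnan(lengths)):
        raise InvalidGranuleError("no through-hilum chord found")
    i = int(np.nanargmax(lengths))   # first occurrence: smallest theta wins
    step = np.pi / _COARSE_DIRECTIONS

    def f(theta: float) -> float:
        val = _chord_lengths(v, h, np.array([theta]))[0]
        return -np.inf if np.isnan(val) else float(val)

    theta = _golden_max(f, thetas[i] - step, thetas[i] + step, _GOLDEN_TOL_RAD)
    u = np.array([np.cos(theta), np.sin(theta)])
    t_min, t_max = _line_crossings(v, h, u[None, :])
    p_neg = h + t_min[0] * u
    p_pos = h + t_max[0] * u
    length = float(t_max[0] - t_min[0])
    # proximal = endpoint nearer the hilum
    if abs(t_min[0]) <= abs(t_max[0]):
        endpoints = (tuple(p_neg), tuple(p_pos))
    else:
        endpoints = (tuple(p_pos), tuple(p_neg))
    return length, endpoints


def max_width_perpendicular(
        contour: GranuleContour,
        length_axis: PointPair) -> tuple[float, PointPair]:
    """Widest chord perpendicular to the length axis.

    The chord is free to sit anywhere along the axis (it need not pass
    through the hilum).  Where a perpendicular line crosses a non-convex
    boundary more than twice, the width at that station is the distance
    between the two extreme intersections.
    """
    e1 = np.asarray(length_axis[0], dtype=float)
    e2 = np.asarray(length_axis[1], dtype=float)
    axis = e2 - e1
    norm = np.hypot(*axis)
    if norm < 1e-9:
        raise InvalidGranuleError("length axis endpoints coincide")
    u = axis / norm
    w = np.array([-u[1], u[0]])   # perpendicular direction
    v = contour.vertices

    proj = v @ u
    t_lo, t_hi = float(proj.min()), float(proj.max())

    def width_at(t: float) -> tuple[float, np.ndarray, np.ndarray]:
        q = t * u
        s_min, s_max = _line_crossings(v, q, w[None, :])
        if np.isnan(s_min[0]):
            return -np.inf, q, q
        return float(s_max[0] - s_min[0]), q + s_min[0] * w, q + s_max[0] * w

    ts = np.linspace(t_lo, t_hi, _COARSE_STATIONS + 2)[1:-1]
    widths = np.array([width_at(t)[0] for t in ts])
    i = int(np.argmax(widths))
    step = (t_hi - t_lo) / (_COARSE_STATIONS + 1)
    t_best = _golden_max(lambda t: width_at(t)[0],
                         ts[i] - step, ts[i] + step,
                         tol=max(norm * 1e-6, 1e-9))
    width, pa, pb = width_at(t_best)
    if widths[i] > width:          # refinement never worsens the coarse best
        width, pa, pb = width_at(ts[i])
    return float(width), (tuple(pa), tuple(pb))


def eccentricity_ratio(hilum: Sequence[float],
                       length_axis: PointPair) -> float:
    """Hilum-to-proximal-end distance over the maximum length, in [0, 0.5]."""
    h = np.asarray(hilum, dtype=float)
    e1 = np.asarray(length_axis[0], dtype=float)
    e2 = np.asarray(length_axis[1], dtype=float)
    total = float(np.hypot(*(e2 - e1)))
    if total < 1e-9:
        raise InvalidGranuleError("zero-length axis")
    d = min(float(np.hypot(*(h - e1))), float(np.hypot(*(h - e2))))
    return min(d / total, 0.5)


def hilum_angle(hilum: Sequence[float], width_chord: PointPair) -> float:
    """Angle at the hilum subtended by the maximum-width chord, degrees.

    180° when the hilum lies on the open chord segment; decreases
    monotonically as the hilum moves away from the chord along its
    perpendicular bisector.
    """
    h = np.asarray(hilum, dtype=float)
    a = np.asarray(width_chord[0], dtype=float) - h
    b = np.asarray(width_chord[1], dtype=float) - h
    if np.hypot(*a) < 1e-12 or np.hypot(*b) < 1e-12:
        raise InvalidGranuleError("hilum coincides with a chord endpoint")
    cross = abs(a[0] * b[1] - a[1] * b[0])
    dot = float(a @ b)
    # arctan2(|cross|, dot) is the vertex angle in [0, 180]; a hilum on the
    # open chord segment gives exactly 180 (opposite rays).
    return float(np.degrees(np.arctan2(cross, dot)))


def measure_granule(contour: GranuleContour,
                    id: str | None = None) -> GranuleMeasurement:
    """Compose the four morphometric operations for one granule.

    If the perpendicular width exceeds the through-hilum length by more
    than 1% a warning is emitted; values are reported as measured, never
    swapped.
    """
    length, axis = max_chord_through_point(contour)
    width, chord = max_width_perpendicular(contour, axis)
    if width > 1.01 * length:
        warnings.warn(
            f"granule {id or contour.id!r}: max width {width:.3f} exceeds "
            f"max length {length:.3f} by more than 1%; reported as measured",
            stacklevel=2)
    er = eccentricity_ratio(contour.hilum, axis)
    ang = hilum_angle(contour.hilum, chord)
    return GranuleMeasurement(
        max_length=length, max_width=width, eccentricity_ratio=er,
        hilum_angle=ang, length_axis=axis, width_chord=chord)


def extract_contour(mask: np.ndarray,
                    pixel_size: float) -> GranuleContour:
    """Boundary polygon (µm) of a single foreground component in a mask.

    Marching-squares boundary at iso-level 0.5; pixel centres sit at
    half-integer µm multiples of ``pixel_size``.  The hilum is left unset.
    """
    from skimage import measure as _skmeasure

    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise InvalidGranuleError("mask must be 2D")
    if not mask.any():
        raise InvalidGranuleError("mask has no foreground component")
    labels, n_comp = _skmeasure.label(mask, return_num=True, connectivity=2)
    if n_comp != 1:
        raise InvalidGranuleError(
            f"mask has {n_comp} components; exactly one required")
    padded = np.pad(mask.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise InvalidGranuleError("no iso-contour found")
    boundary = max(contours, key=len)
    rows = boundary[:, 0] - 1.0
    cols = boundary[:, 1] - 1.0
    xy = np.column_stack([(cols + 0.5) * pixel_size,
                          (rows + 0.5) * pixel_size])
    return GranuleContour(xy, hilum=None)
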