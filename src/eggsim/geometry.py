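"""Tube-surface construction from a discrete centerline.

The gastrointestinal organ is idealised as a smooth tube: an ordered polyline
of centerline points ``C_n`` (cm) with a per-point tube radius ``r_n`` (cm).
At every centerline point a *vertex circle* of ``M`` samples is placed in the
plane perpendicular to the local segment direction; adjoining circles are then
connected into quadrilateral *microregions*.  Each microregion later carries
one electric dipole, so the mesh doubles as the discrete dipole support of the
annular depolarization band.

All lengths are in centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import (
    DegenerateQuadWarning,
    DegenerateSegmentError,
    InvalidParameterError,
)

__all__ = [
    "Centerline",
    "TubeMesh",
    "Microregion",
    "make_vertex_circle",
    "orient_and_place_circle",
    "build_tube_mesh",
    "microregion_geometry",
]


# --------------------------------------------------------------------------
# centerline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline with a tube radius at every point.

    Parameters
    ----------
    points
        Array of shape ``(N, 3)``, centimetres, ``N >= 2``.  Consecutive
        points must be distinct so that every segment has a direction.
    radii
        Array of shape ``(N,)``, positive tube radii in centimetres.
    """

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise InvalidParameterError("centerline points must have shape (N, 3)")
        if points.shape[0] < 2:
            raise InvalidParameterError("a centerline needs at least two points")
        if radii.shape != (points.shape[0],):
            raise InvalidParameterError("need exactly one radius per centerline point")
        if not np.all(np.isfinite(points)) or not np.all(np.isfinite(radii)):
            raise InvalidParameterError("centerline coordinates must be finite")
        if np.any(radii <= 0.0):
            raise InvalidParameterError("all tube radii must be positive")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg == 0.0):
            idx = int(np.nonzero(seg == 0.0)[0][0])
            raise DegenerateSegmentError(
                f"centerline points {idx} and {idx + 1} coincide"
            )
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "radii", radii)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @cached_property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative polyline arc length at each point (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(seg)))

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Centerline":
        """Return a rigidly transformed copy (rotation applied first)."""
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return Centerline(pts, self.radii.copy())


# --------------------------------------------------------------------------
# vertex circles
# --------------------------------------------------------------------------

def make_vertex_circle(radius: float, samples: int) -> np.ndarray:
    """Sample a circle of given radius in the ``z = 0`` plane.

    Returns ``samples`` points ``(r cos θ_m, r sin θ_m, 0)`` with
    ``θ_m = 2π m / M`` for ``m = 1 … M``.
    """
    if not radius > 0.0:
        raise InvalidParameterError(f"circle radius must be positive, got {radius}")
    if samples < 3:
        raise InvalidParameterError(f"need at least 3 circle samples, got {samples}")
    theta = 2.0 * np.pi * np.arange(1, samples + 1) / samples
    return np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), np.zeros(samples))
    )


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_VERTICAL_TOL = 1e-12


def segment_rotation(direction: np.ndarray,
                     fallback_azimuth: float = 0.0) -> tuple[np.ndarray, float]:
    """Rotation mapping the +z axis onto ``direction``.

    The map is the two-angle elevation/azimuth construction
    ``R = R_z(β) · R_y(γ)`` with ``γ`` the polar angle of the segment from +z
    and ``β = atan2(Δy, Δx)`` its azimuth, both from the full-quadrant
    arctangent.  For a vertical segment the azimuth is undefined; the caller's
    ``fallback_azimuth`` (normally the previous circle's azimuth) is reused so
    the circumferential parameterisation does not flip along the tube.

    Returns the 3x3 rotation and the azimuth actually used.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0 or not np.all(np.isfinite(d)):
        raise DegenerateSegmentError("segment direction has zero length")
    dx, dy, dz = d / norm
    horizontal = float(np.hypot(dx, dy))
    gamma = float(np.arctan2(horizontal, dz))
    beta = float(np.arctan2(dy, dx)) if horizontal > _VERTICAL_TOL else fallback_azimuth
    return _rot_z(beta) @ _rot_y(gamma), beta


def orient_and_place_circle(local_circle: np.ndarray,
                            c_n: np.ndarray,
                            c_next: np.ndarray,
                            fallback_azimuth: float = 0.0) -> np.ndarray:
    """Rotate a z-plane vertex circle perpendicular to ``c_next - c_n`` and
    translate it to ``c_n``."""
    c_n = np.asarray(c_n, dtype=float)
    rotation, _ = segment_rotation(np.asarray(c_next, dtype=float) - c_n,
                                   fallback_azimuth)
    return np.asarray(local_circle, dtype=float) @ rotation.T + c_n


# --------------------------------------------------------------------------
# tube mesh
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeMesh:
    """Quad-meshed tube surface: ``N`` oriented vertex circles of ``M`` samples.

    ``vertices[n, m]`` is vertex ``m`` of circle ``n``.  Ring ``n`` is the band
    of ``M`` quads between circles ``n`` and ``n + 1``; there are ``N - 1``
    rings.  The circumferential index is cyclic.
    """

    vertices: np.ndarray       # (N, M, 3) cm
    centers: np.ndarray        # (N, 3) circle centers = centerline points
    radii: np.ndarray          # (N,)
    ring_widths: np.ndarray    # (N - 1,) axial spacing between circle centers

    @property
    def n_circles(self) -> int:
        return self.vertices.shape[0]

    @property
    def circle_samples(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_rings(self) -> int:
        return self.n_circles - 1

    @cached_property
    def arc_lengths(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.ring_widths)))

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    @cached_property
    def ring_center_arclens(self) -> np.ndarray:
        """Arc-length coordinate of each ring's axial midpoint."""
        return self.arc_lengths[:-1] + 0.5 * self.ring_widths

    def quad_corners(self, n: int) -> tuple[np.ndarray, ...]:
        """Corner arrays ``(C_mn, C_m+1n, C_m+1n+1, C_mn+1)`` for ring ``n``,
        each of shape ``(M, 3)``; the circumferential index wraps."""
        if not 0 <= n < self.n_rings:
            raise IndexError(f"ring index {n} out of range [0, {self.n_rings})")
        a = self.vertices[n]
        b = np.roll(a, -1, axis=0)
        d = self.vertices[n + 1]
        c = np.roll(d, -1, axis=0)
        return a, b, c, d

    def ring_geometry(self, n: int) -> dict[str, np.ndarray]:
        """Vectorised microregion geometry for ring ``n``.

        Returns area vectors (cross product of the two quad edges), scalar
        areas, diagonal-midpoint centers, outward unit normals, and the
        circumferential chord lengths used to convert a dipole moment line
        density into per-quad moments.  Results are cached per ring.
        """
        cache = self.__dict__.setdefault("_ring_cache", {})
        if n in cache:
            return cache[n]
        a, b, c, d = self.quad_corners(n)
        area_vec = np.cross(b - a, d - a)
        area = np.linalg.norm(area_vec, axis=1)
        center = 0.5 * (c + a)
        normal = np.zeros_like(area_vec)
        ok = area > 0.0
        normal[ok] = area_vec[ok] / area[ok, None]
        # orient outward: away from the ring's axial midpoint on the centerline
        mid = 0.5 * (self.centers[n] + self.centers[n + 1])
        flip = np.einsum("ij,ij->i", normal, center - mid) < 0.0
        normal[flip] *= -1.0
        geom = {
            "area_vectors": area_vec,
            "areas": area,
            "centers": center,
            "outward_normals": normal,
            "chords": np.linalg.norm(b - a, axis=1),
        }
        cache[n] = geom
        return geom

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TubeMesh":
        """Rigidly transformed copy (rotation first, then translation)."""
        verts, cents = self.vertices, self.centers
        if rotation is not None:
            rot = np.asarray(rotation, dtype=float)
            verts = verts @ rot.T
            cents = cents @ rot.T
        if translation is not None:
            t = np.asarray(translation, dtype=float)
            verts = verts + t
            cents = cents + t
        return TubeMesh(verts, cents, self.radii.copy(), self.ring_widths.copy())


def build_tube_mesh(centerline: Centerline, circle_samples: int) -> TubeMesh:
    """Sweep oriented vertex circles along a centerline into a quad tube mesh.

    Circle ``n`` is oriented perpendicular to segment ``n -> n + 1``; the last
    circle reuses the direction of the final segment so the tube end stays
    continuous.  Vertical segments inherit the previous circle's azimuth.
    """
    if circle_samples < 3:
        raise InvalidParameterError("circle_samples must be at least 3")
    pts = centerline.points
    n_pts = centerline.n_points
    vertices = np.empty((n_pts, circle_samples, 3))
    azimuth = 0.0
    for n in range(n_pts):
        j = min(n, n_pts - 2)
        direction = pts[j + 1] - pts[j]
        try:
            rotation, azimuth = segment_rotation(direction, azimuth)
        except DegenerateSegmentError as exc:  # pragma: no cover - caught upstream
            raise DegenerateSegmentError(f"segment {j} -> {j + 1}: {exc}") from exc
        local = make_vertex_circle(float(centerline.radii[n]), circle_samples)
        vertices[n] = local @ rotation.T + pts[n]
    ring_widths = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return TubeMesh(vertices, pts.copy(), centerline.radii.copy(), ring_widths)


# --------------------------------------------------------------------------
# microregions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Microregion:
    """One quad face of the tube mesh: the discrete dipole carrier.

    ``area_vector`` is the cross product of the two quad edge vectors leaving
    corner ``(m, n)``; ``center`` is the midpoint of the diagonal corners
    ``(m, n)`` and ``(m + 1, n + 1)``.  ``normal`` points outward (away from
    the centerline); it is zero for a degenerate (pinched) quad.
    """

    m: int
    n: int
    area_vector: np.ndarray   # cm^2
    area: float               # |area_vector|, cm^2
    normal: np.ndarray        # unit, outward
    center: np.ndarray        # cm
    chord: float              # circumferential edge length, cm


def microregion_geometry(mesh: TubeMesh, m: int, n: int) -> Microregion:
    """Geometry of the quad at circumferential index ``m`` (cyclic) of ring
    ``n``.  Indices are 0-based; ``m`` must lie in ``[0, M)``."""
    if not 0 <= m < mesh.circle_samples:
        raise IndexError(
            f"circumferential index {m} out of range [0, {mesh.circle_samples})"
        )
    geom = mesh.ring_geometry(n)  # validates n
    area = float(geom["areas"][m])
    if area == 0.0:
        warnings.warn(
            f"microregion (m={m}, n={n}) is degenerate (zero area); "
            "it carries no dipole",
            DegenerateQuadWarning,
            stacklevel=2,
        )
    return Microregion(
        m=m,
        n=n,
        area_vector=geom["area_vectors"][m].copy(),
        area=area,
        normal=geom["outward_normals"][m].copy(),
        center=geom["centers"][m].copy(),
        chord=float(geom["chords"][m]),
    )
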