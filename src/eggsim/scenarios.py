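"""Built-in benchmark scenarios.

Three deterministic fixtures exercise the simulator:

* ``cylinder`` — upright cylinder, constant-speed band, the classical
  intestine benchmark (analytic counterpart: the mathematical cylinder
  model);
* ``conoid`` — circular-arc centerline with a linearly tapering tube radius,
  exponentially saturating band motion, the classical stomach benchmark
  (analytic counterpart: the conoidal dipole model);
* ``pseudocolon`` — a colon-like 3D centerline with two sharp flexures,
  out-of-plane displacement and a periodically modulated tube radius; no
  analytic counterpart exists, which is precisely the case the meshed model
  is for.

Geometry is stated internally in centimetres; builders that accept printed
metre-valued inputs convert and log the conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .dynamics import ConoidExponentialMotion, ConstantLinearMotion
from .errors import InvalidGeometryError, InvalidParameterError
from .field import DipoleConstants
from .geometry import Centerline, TubeMesh, build_tube_mesh

__all__ = [
    "Scenario",
    "make_cylinder_scenario",
    "make_conoid_scenario",
    "make_pseudocolon_scenario",
    "builtin_scenarios",
    "get_scenario",
]

log = logging.getLogger(__name__)

#: minimum allowed gap (cm) between an electrode and the tube surface
SURFACE_CLEARANCE = 1e-3


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable simulation setup."""

    name: str
    centerline: Centerline
    circle_samples: int                 # M
    constants: DipoleConstants
    measurement: np.ndarray             # E1, cm
    reference: np.ndarray               # E0, cm
    motion: object                      # any object with .position(t) -> cm
    band_width: float | None = None     # cm; None = one ring width
    sampling_rate: float = 10.0         # Hz
    duration: float = 60.0              # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurement",
                           np.asarray(self.measurement, dtype=float))
        object.__setattr__(self, "reference",
                           np.asarray(self.reference, dtype=float))
        if self.circle_samples < 3:
            raise InvalidParameterError("circle_samples must be at least 3")
        if self.band_width is not None and self.band_width <= 0.0:
            raise InvalidParameterError("band width must be positive")
        if self.sampling_rate <= 0.0 or self.duration <= 0.0:
            raise InvalidParameterError("sampling rate and duration must be positive")
        if np.allclose(self.measurement, self.reference):
            raise InvalidParameterError(
                "measurement and reference electrodes must differ"
            )

    @property
    def ring_width(self) -> float:
        """Mean axial spacing between adjacent vertex circles (cm)."""
        return self.centerline.total_length / (self.centerline.n_points - 1)

    def effective_band_width(self, mesh: TubeMesh | None = None) -> float:
        if self.band_width is not None:
            return self.band_width
        if mesh is not None:
            return float(np.mean(mesh.ring_widths))
        return self.ring_width

    def build_mesh(self, circle_samples: int | None = None) -> TubeMesh:
        m = circle_samples if circle_samples is not None else self.circle_samples
        return build_tube_mesh(self.centerline, m)

    def surface_gap(self, position, mesh: TubeMesh | None = None) -> float:
        """Distance (cm) from a point to the nearest microregion center.

        This is the quantity that controls the dipole-sum singularity: an
        electrode placed on the tube surface sits within a fraction of a quad
        diagonal of some microregion center.  Positions inside or outside the
        tube volume are both fine as long as they keep clear of the surface.
        """
        if mesh is None:
            mesh = self.build_mesh()
        pos = np.asarray(position, dtype=float)
        gap = np.inf
        for n in range(mesh.n_rings):
            centers = mesh.ring_geometry(n)["centers"]
            gap = min(gap, float(np.min(np.linalg.norm(centers - pos, axis=1))))
        return gap

    def validate(self, mesh: TubeMesh | None = None) -> None:
        """Check that both electrodes sit clear of the tube surface."""
        if mesh is None:
            mesh = self.build_mesh()
        for label, pos in (("measurement", self.measurement),
                           ("reference", self.reference)):
            gap = self.surface_gap(pos, mesh)
            if gap < SURFACE_CLEARANCE:
                raise InvalidGeometryError(
                    f"{label} electrode of scenario {self.name!r} lies on the "
                    f"tube surface (gap {gap:.2e} cm)"
                )

    def with_overrides(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# cylinder benchmark
# --------------------------------------------------------------------------

def make_cylinder_scenario(n_circles: int = 910,
                           circle_samples: int = 100,
                           length_m: float = 0.10,
                           band_radius_m: float = 0.0125,
                           freq_cpm: float = 5.4,
                           duration: float = 60.0) -> Scenario:
    """Upright-cylinder benchmark.

    A 0.10 m cylinder of radius 0.0125 m along +z, 910 vertex circles (ring
    width 0.00011 m), band moving at the ECA frequency 5.4 cycles/min,
    |P| = 0.45e-7 C/cm, ε = 2.65e-8 C²/(N·cm²); electrodes on the cylinder
    axis at z = 4.0 (reference) and z = 4.2 (measurement) cm.
    """
    length = 100.0 * length_m
    radius = 100.0 * band_radius_m
    log.info("cylinder scenario: converted l = %g m -> %g cm, R0 = %g m -> %g cm",
             length_m, length, band_radius_m, radius)
    z = np.linspace(0.0, length, n_circles)
    points = np.column_stack((np.zeros(n_circles), np.zeros(n_circles), z))
    centerline = Centerline(points, np.full(n_circles, radius))
    return Scenario(
        name="cylinder",
        centerline=centerline,
        circle_samples=circle_samples,
        constants=DipoleConstants(moment_density=0.45e-7, permittivity=2.65e-8),
        measurement=np.array([0.0, 0.0, 4.2]),
        reference=np.array([0.0, 0.0, 4.0]),
        motion=ConstantLinearMotion(length=length, freq_cpm=freq_cpm),
        sampling_rate=10.0,
        duration=duration,
    )


# --------------------------------------------------------------------------
# conoid benchmark
# --------------------------------------------------------------------------

def make_conoid_scenario(n_circles: int = 201,
                         circle_samples: int = 100,
                         arc_radius: float = 10.0,
                         arc_span: float = 1.5,
                         r_start: float = 3.0,
                         r_end: float = 1.0,
                         duration: float = 80.0) -> Scenario:
    """Circular-arc (conoidal stomach) benchmark.

    The centerline is an arc of radius R = 10 cm in the yz-plane starting on
    the y-axis, spanning ``arc_span`` radians (default 1.5, slightly under a
    quarter turn, giving a band traversal of about 20 s under the
    exponential motion law, so successive cycle turns fall near 20/40/60 s).
    The tube radius tapers linearly from ``r_start`` to ``r_end``.
    |P| = 2.2e-6 C/cm, ε = 2.21e-8 C²/(N·cm²); electrodes at
    (0, 4.8, 10.9) (reference) and (0, 3.8, 11.1) cm (measurement).
    """
    alpha = np.linspace(0.0, arc_span, n_circles)
    points = arc_radius * np.column_stack(
        (np.zeros(n_circles), np.cos(alpha), np.sin(alpha))
    )
    radii = np.linspace(r_start, r_end, n_circles)
    centerline = Centerline(points, radii)
    return Scenario(
        name="conoid",
        centerline=centerline,
        circle_samples=circle_samples,
        constants=DipoleConstants(moment_density=2.2e-6, permittivity=2.21e-8),
        measurement=np.array([0.0, 3.8, 11.1]),
        reference=np.array([0.0, 4.8, 10.9]),
        motion=ConoidExponentialMotion(path_length=centerline.total_length),
        sampling_rate=10.0,
        duration=duration,
    )


# --------------------------------------------------------------------------
# pseudocolon benchmark
# --------------------------------------------------------------------------

# Waypoints (cm) of a colon-like course: ascending limb, hepatic-flexure-like
# sharp bend, transverse limb with out-of-plane (y) displacement,
# splenic-flexure-like bend, descending limb.  Purely an emulation of the
# colon silhouette; the spline through these points is rescaled so the
# sampled polyline is exactly 15 cm long.
_COLON_WAYPOINTS = np.array([
    [4.6, 0.0, 0.8],
    [4.5, 0.3, 2.6],
    [4.1, 0.5, 4.2],
    [3.0, 0.4, 4.9],
    [1.6, 0.2, 4.8],
    [0.7, -0.1, 3.9],
    [0.5, -0.3, 2.2],
    [0.8, -0.4, 0.6],
])

#: number of full periods of the tube-radius modulation along the colon;
#: the haustra-like waviness tilts the microregion normals back and forth,
#: which is what makes the simulated potential alternate in sign
_COLON_RADIUS_PERIODS = 4


def _pseudocolon_centerline(n_circles: int, total_length: float) -> Centerline:
    """Deterministic colon-like centerline of exact polyline length."""
    chords = np.linalg.norm(np.diff(_COLON_WAYPOINTS, axis=0), axis=1)
    u = np.concatenate(([0.0], np.cumsum(chords))) / np.sum(chords)
    spline = CubicSpline(u, _COLON_WAYPOINTS, axis=0)
    dense = spline(np.linspace(0.0, 1.0, 4001))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    # equal-arc-length resample, then rescale so the polyline length is exact
    targets = np.linspace(0.0, cum[-1], n_circles)
    pts = np.column_stack([np.interp(targets, cum, dense[:, k]) for k in range(3)])
    poly_len = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    pts *= total_length / poly_len
    n = np.arange(n_circles)
    radii = 2.0 + 0.5 * np.sin(
        2.0 * np.pi * _COLON_RADIUS_PERIODS * n / (n_circles - 1)
    )
    return Centerline(pts, radii)


def make_pseudocolon_scenario(n_circles: int = 81,
                              circle_samples: int = 100,
                              total_length: float = 15.0,
                              freq_cpm: float = 5.4,
                              duration: float = 30.0) -> Scenario:
    """Colon-like benchmark with bends and a modulated tube radius.

    15 cm of colon-like centerline sampled at 81 points, tube radius
    oscillating sinusoidally between 1.5 and 2.5 cm (the sample grid hits the
    extrema exactly), |P| = 0.45e-7 C/cm, ε = 2.21e-8 C²/(N·cm²); electrodes
    at (3.19, 0.25, 7.36) (reference) and (2.62, 0.25, 7.33) cm
    (measurement).  The band travels at a constant 5.4 cycles/min — one ECA
    cycle per 60/5.4 s traversal — since no analytic motion law exists for
    this geometry.
    """
    centerline = _pseudocolon_centerline(n_circles, total_length)
    return Scenario(
        name="pseudocolon",
        centerline=centerline,
        circle_samples=circle_samples,
        constants=DipoleConstants(moment_density=0.45e-7, permittivity=2.21e-8),
        measurement=np.array([2.62, 0.25, 7.33]),
        reference=np.array([3.19, 0.25, 7.36]),
        motion=ConstantLinearMotion(length=total_length, freq_cpm=freq_cpm),
        sampling_rate=10.0,
        duration=duration,
    )


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_BUILDERS = {
    "cylinder": make_cylinder_scenario,
    "conoid": make_conoid_scenario,
    "pseudocolon": make_pseudocolon_scenario,
}


def builtin_scenarios() -> tuple[str, ...]:
    return tuple(_BUILDERS)


def get_scenario(name: str, **params) -> Scenario:
    """Build a named built-in scenario, forwarding parameter overrides."""
    if name not in _BUILDERS:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; built-ins are {sorted(_BUILDERS)}"
        )
    return _BUILDERS[name](**params)
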