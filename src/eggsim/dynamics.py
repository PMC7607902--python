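"""Motion laws of the annular depolarization band.

The band is a contiguous set of mesh rings; its leading edge sits at an
arc-length position ``s(t)`` along the centerline.  Two closed-form motion
laws are provided:

* ``constant_linear`` — the cylinder convention ``z(t) = l · f · t`` with
  ``f`` the slow-wave (ECA) frequency in cycles/min, periodic with period
  ``60 / f`` seconds.
* ``conoid_exponential`` — the conoidal-stomach velocity law
  ``v(t) = 0.00825 - 0.00575 · exp(-0.362 t)`` (model length units per
  second), integrated in closed form to a displacement ``l(t)``.

A ``table`` law interpolates a user-supplied time/position table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError
from .geometry import TubeMesh

__all__ = [
    "BandState",
    "cylinder_position",
    "conoid_velocity",
    "conoid_displacement",
    "conoid_angle",
    "position_to_active_rings",
    "ConstantLinearMotion",
    "ConoidExponentialMotion",
    "TableMotion",
    "make_motion",
]

# conoidal velocity law coefficients (model length units / s)
CONOID_V_LIMIT = 0.00825
CONOID_V_DROP = 0.00575
CONOID_RATE = 0.362


@dataclass(frozen=True)
class BandState:
    """Snapshot of the band at one sample instant."""

    time: float                 # s
    position: float             # arc length of the band's leading edge, cm
    ring_indices: np.ndarray    # contiguous active rings (may be empty)
    band_width: float           # cm


def cylinder_position(t: float, length: float, freq_cpm: float) -> float:
    """Band position ``z(t) = l · f · t`` wrapped to ``[0, l)``.

    ``freq_cpm`` is in cycles per minute, so one traversal of the cylinder
    takes ``60 / f`` seconds.
    """
    if t < 0.0:
        raise InvalidParameterError("time must be non-negative")
    if length <= 0.0 or freq_cpm <= 0.0:
        raise InvalidParameterError("length and frequency must be positive")
    return float((length * (freq_cpm / 60.0) * t) % length)


def conoid_velocity(t):
    """Band propagation speed of the conoidal stomach model (units/s).

    Strictly increasing from 0.0025 at ``t = 0`` toward the limit 0.00825.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    out = CONOID_V_LIMIT - CONOID_V_DROP * np.exp(-CONOID_RATE * t)
    return float(out) if out.ndim == 0 else out


def conoid_displacement(t):
    """Closed-form integral of :func:`conoid_velocity` from 0 to ``t``."""
    t = np.asarray(t, dtype=float)
    out = CONOID_V_LIMIT * t + (CONOID_V_DROP / CONOID_RATE) * (
        np.exp(-CONOID_RATE * t) - 1.0
    )
    return float(out) if out.ndim == 0 else out


def conoid_angle(t, arc_radius: float):
    """Angular position ``α(t) = l(t) / R`` of the band center (radians).

    ``arc_radius`` must be in the same length unit as the displacement.
    """
    if arc_radius <= 0.0:
        raise InvalidParameterError("arc radius must be positive")
    return conoid_displacement(t) / arc_radius


def position_to_active_rings(mesh: TubeMesh, s: float,
                             band_width: float) -> np.ndarray:
    """Rings whose axial midpoint lies in the half-open window ``[s, s + w)``.

    If the window straddles ring boundaries without containing any midpoint
    (possible when ``w`` is at most one ring width) the nearest ring is
    returned, so an on-tube band is never empty.  A position off the tube
    (``s < 0`` or ``s >= total length``) yields an empty set.
    """
    if band_width <= 0.0:
        raise InvalidParameterError("band width must be positive")
    if s < 0.0 or s >= mesh.total_length:
        return np.empty(0, dtype=int)
    centers = mesh.ring_center_arclens
    sel = np.nonzero((centers >= s) & (centers < s + band_width))[0]
    if sel.size == 0:
        sel = np.array([int(np.argmin(np.abs(centers - s)))])
    return sel


# --------------------------------------------------------------------------
# motion-law objects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantLinearMotion:
    """Constant-speed periodic traversal (cylinder convention)."""

    length: float       # cm
    freq_cpm: float     # cycles / min

    @property
    def period(self) -> float:
        return 60.0 / self.freq_cpm

    def position(self, t: float) -> float:
        return cylinder_position(t, self.length, self.freq_cpm)


@dataclass(frozen=True)
class ConoidExponentialMotion:
    """Exponentially saturating traversal (conoidal stomach convention).

    The velocity law is stated in metres per second; ``unit_scale`` converts
    its displacement to the centimetre world of the mesh (default 100).  The
    next cycle begins as soon as the band reaches the end of the path
    (``dwell = 0``), with time — and hence the velocity ramp-up — restarting.
    """

    path_length: float          # cm
    unit_scale: float = 100.0   # displacement units -> cm
    dwell: float = 0.0          # pause at the end of each cycle, s

    def __post_init__(self) -> None:
        if self.path_length <= 0.0 or self.unit_scale <= 0.0 or self.dwell < 0.0:
            raise InvalidParameterError("invalid conoid motion parameters")

    @property
    def cycle_period(self) -> float:
        """Time for one full traversal, from ``l(T) = path_length``."""
        cached = self.__dict__.get("_period")
        if cached is None:
            target = self.path_length / self.unit_scale
            upper = target / CONOID_V_LIMIT + 2.0 / CONOID_RATE + 1.0
            cached = brentq(lambda t: conoid_displacement(t) - target, 0.0, upper)
            self.__dict__["_period"] = cached
        return float(cached)

    def position(self, t: float) -> float:
        if t < 0.0:
            raise InvalidParameterError("time must be non-negative")
        cycle = self.cycle_period + self.dwell
        tau = t % cycle
        if tau >= self.cycle_period:  # dwelling off the tube end
            return self.path_length
        return float(self.unit_scale * conoid_displacement(tau))

    def cycle_time(self, t: float) -> float:
        """Time elapsed since the start of the current cycle."""
        if t < 0.0:
            raise InvalidParameterError("time must be non-negative")
        return t % (self.cycle_period + self.dwell)


@dataclass(frozen=True)
class TableMotion:
    """Piecewise-linear interpolation of a user-supplied time/position table."""

    times: np.ndarray       # s, strictly increasing
    positions: np.ndarray   # cm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or times.shape != positions.shape or times.size < 2:
            raise InvalidParameterError("motion table needs matching 1D columns")
        if np.any(np.diff(times) <= 0.0):
            raise InvalidParameterError("motion table times must be increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    def position(self, t: float) -> float:
        return float(np.interp(t, self.times, self.positions))


def make_motion(law: str, **params):
    """Construct a motion law from its configuration key."""
    laws = {
        "constant_linear": ConstantLinearMotion,
        "conoid_exponential": ConoidExponentialMotion,
        "table": TableMotion,
    }
    if law not in laws:
        raise InvalidParameterError(
            f"unknown motion law {law!r}; choose from {sorted(laws)}"
        )
    return laws[law](**params)
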