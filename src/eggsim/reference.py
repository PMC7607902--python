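"""Conventional analytic dipole models used as oracles and baselines.

Two classical models describe the travelling annular band without any surface
mesh:

* the **mathematical cylinder model** — the band is a thin ring of radial
  dipoles on an upright cylinder, the potential a closed double integral over
  the band's angular and axial extent, evaluated here by composite
  trapezoid (angular, periodic) × Simpson (axial) quadrature;
* the **conoidal dipole model** — the band travels along a circular arc of
  radius R in the yz-plane with a time-varying band radius r(t); the
  potential is a single angular integral built from the model's analytic
  sub-expressions (chord length OL, azimuth φ(t, θ), and the electrode
  distance ρ(t, θ)).

Both are implemented independently of the meshed model so they can serve as
cross-checks.  Sign convention: with the band's dipoles pointing inward and a
positive ``1/4πε`` prefactor, a single electrode sees a positive excursion as
the band passes — the same convention as :mod:`eggsim.field`, so waveforms
from the two routes are directly comparable.

The conoidal potential formula circulates in a typographically garbled form;
this implementation assembles it from the unambiguous sub-expressions (the
triangle relation for OL, the arcsine azimuth, the spherical distance ρ) and
the stated prefactor ``|P| δ r(t) α(t) tan α_c``.  A stray θ sometimes shown
under the integrand's denominator is treated as a typesetting artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import simpson

from .dynamics import ConoidExponentialMotion, ConstantLinearMotion, cylinder_position
from .errors import (
    ComparisonError,
    InvalidGeometryError,
    InvalidParameterError,
    NumericError,
)
from .field import EGGSignal

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

__all__ = [
    "CylinderModelParams",
    "ConoidModelParams",
    "cylinder_potential",
    "conoid_potential",
    "cylinder_reference_signal",
    "conoid_reference_signal",
    "compare_models",
    "cartesian_to_cylindrical",
    "cylindrical_to_cartesian",
    "cartesian_to_conoid",
    "conoid_to_cartesian",
]


# --------------------------------------------------------------------------
# electrode coordinate conversions
# --------------------------------------------------------------------------

def cartesian_to_cylindrical(position) -> tuple[float, float, float]:
    """Cartesian (x, y, z) -> cylinder-model coordinates (z_p, h, θ)."""
    x, y, z = np.asarray(position, dtype=float)
    return float(z), float(np.hypot(x, y)), float(np.arctan2(y, x))


def cylindrical_to_cartesian(zp: float, h: float, theta: float) -> np.ndarray:
    return np.array([h * np.cos(theta), h * np.sin(theta), zp])


def cartesian_to_conoid(position) -> tuple[float, float, float]:
    """Cartesian (x, y, z) -> conoid-model coordinates (OQ, φ_c, α_c).

    φ_c is the azimuth of the point out of the yz-plane (measured from the
    y-axis in the xy-sense); α_c is its elevation from the y-axis within the
    yz-plane.  The conversion round-trips with :func:`conoid_to_cartesian`.
    """
    p = np.asarray(position, dtype=float)
    oq = float(np.linalg.norm(p))
    if oq == 0.0:
        raise InvalidGeometryError("electrode at the conoid origin")
    phi_c = float(np.arcsin(np.clip(p[0] / oq, -1.0, 1.0)))
    alpha_c = float(np.arctan2(p[2], p[1]))
    return oq, phi_c, alpha_c


def conoid_to_cartesian(oq: float, phi_c: float, alpha_c: float) -> np.ndarray:
    return oq * np.array([
        np.sin(phi_c),
        np.cos(phi_c) * np.cos(alpha_c),
        np.cos(phi_c) * np.sin(alpha_c),
    ])


# --------------------------------------------------------------------------
# conventional model 1: mathematical cylinder
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderModelParams:
    """Parameters of the analytic cylinder band model.

    The electrode is given in the model's native cylindrical coordinates
    ``(electrode_zp, electrode_h, electrode_theta)``.  ``dipole_density`` is
    the surface density |D| (moment per unit band area); for cross-checks
    against the meshed model use ``|D| = |P| / band_width``.
    """

    length: float               # cylinder length l, cm
    freq_cpm: float             # ECA frequency f, cycles/min
    band_radius: float          # R0, cm
    band_width: float           # δ, cm
    dipole_density: float       # |D|
    permittivity: float         # ε, C²/(N·cm²)
    electrode_zp: float = 0.0
    electrode_h: float = 0.0
    electrode_theta: float = 0.0
    n_angular: int = 720        # trapezoid points over Θ ∈ [0, 2π)
    n_axial: int = 64           # Simpson intervals over the band width

    def __post_init__(self) -> None:
        if min(self.length, self.freq_cpm, self.band_radius,
               self.band_width, self.dipole_density, self.permittivity) <= 0.0:
            raise InvalidParameterError("cylinder model parameters must be positive")
        if self.n_angular < 8 or self.n_axial < 2:
            raise InvalidParameterError("quadrature resolution too coarse")


def cylinder_potential(params: CylinderModelParams, t: float) -> float:
    """Single-electrode potential of the cylinder model at time ``t``.

    Composite quadrature of the model's double integral: periodic trapezoid
    over the band angle Θ and Simpson over the axial band extent
    ``[z(t), z(t) + δ]``.  The integrand carries the model's slant weight
    ``z / sqrt(R0² + z²)``, which is why values very near the origin
    (``z ≈ 0``) are unreliable; a warning is emitted there.
    """
    z0 = cylinder_position(t, params.length, params.freq_cpm)
    if z0 < params.band_radius:
        warnings.warn(
            "annular band close to the cylinder origin; the analytic model "
            "is inaccurate there",
            stacklevel=2,
        )
    r0, h = params.band_radius, params.electrode_h
    zp, th = params.electrode_zp, params.electrode_theta
    n_ang = params.n_angular
    big_theta = 2.0 * np.pi * np.arange(n_ang) / n_ang          # periodic grid
    z = np.linspace(z0, z0 + params.band_width, params.n_axial + 1)
    cos_dt = np.cos(big_theta - th)[:, None]                     # (n_ang, 1)
    zz = z[None, :]                                              # (1, n_z+1)
    dist_sq = (zz ** 2 + zp ** 2 + r0 ** 2 + h ** 2
               - 2.0 * (zz * zp + r0 * h * cos_dt))
    dist_sq = np.maximum(dist_sq, 1e-300)
    integrand = (r0 * zz * (r0 - h * cos_dt)
                 / (dist_sq ** 1.5 * np.sqrt(r0 ** 2 + zz ** 2)))
    inner = simpson(integrand, x=z, axis=1)                      # axial first
    value = float(np.sum(inner)) * (2.0 * np.pi / n_ang)         # periodic trapezoid
    if not np.isfinite(value):
        raise NumericError("cylinder-model quadrature did not converge")
    return params.dipole_density * value / (4.0 * np.pi * params.permittivity)


def cylinder_reference_signal(scenario: "Scenario", times,
                              n_angular: int | None = None,
                              n_axial: int | None = None) -> EGGSignal:
    """Differential EGG of the analytic cylinder model on a scenario's
    parameters, evaluated at the given sample times."""
    motion = scenario.motion
    if not isinstance(motion, ConstantLinearMotion):
        raise InvalidParameterError(
            "cylinder reference model requires a constant_linear motion law"
        )
    times = np.asarray(times, dtype=float)
    ring_width = scenario.centerline.total_length / (scenario.centerline.n_points - 1)
    base = CylinderModelParams(
        length=motion.length,
        freq_cpm=motion.freq_cpm,
        band_radius=float(scenario.centerline.radii[0]),
        band_width=scenario.band_width if scenario.band_width else ring_width,
        dipole_density=scenario.constants.moment_density
        / (scenario.band_width if scenario.band_width else ring_width),
        permittivity=scenario.constants.permittivity,
    )
    if n_angular is not None:
        base = replace(base, n_angular=n_angular)
    if n_axial is not None:
        base = replace(base, n_axial=n_axial)
    signals = {}
    for name, pos in (("v1", scenario.measurement), ("v0", scenario.reference)):
        zp, h, th = cartesian_to_cylindrical(pos)
        p = replace(base, electrode_zp=zp, electrode_h=h, electrode_theta=th)
        signals[name] = np.array([cylinder_potential(p, float(t)) for t in times])
    sr = 1.0 / float(times[1] - times[0]) if times.size > 1 else scenario.sampling_rate
    return EGGSignal(times=times, v1=signals["v1"], v0=signals["v0"],
                     sampling_rate=sr)


# --------------------------------------------------------------------------
# conventional model 2: conoidal dipole model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConoidModelParams:
    """Parameters of the analytic conoidal band model.

    The band center sits at distance ``arc_radius`` (R) from the origin at
    elevation α(t) in the yz-plane; the band radius tapers linearly from
    ``r_start`` to ``r_end`` over the traversed arc (``path_length``).  The
    electrode is given in the model's native coordinates ``(OQ, φ_c, α_c)``.
    """

    arc_radius: float           # R, cm
    r_start: float              # band radius at the arc start, cm
    r_end: float                # band radius at the arc end, cm
    path_length: float          # traversed arc length, cm
    band_width: float           # δ, cm
    moment_density: float       # |P|, C/cm
    permittivity: float         # ε, C²/(N·cm²)
    electrode_oq: float
    electrode_phi_c: float
    electrode_alpha_c: float
    motion: ConoidExponentialMotion | None = None
    n_angular: int = 720

    def __post_init__(self) -> None:
        if min(self.arc_radius, self.r_start, self.r_end, self.path_length,
               self.band_width, self.moment_density, self.permittivity) <= 0.0:
            raise InvalidParameterError("conoid model parameters must be positive")
        if max(self.r_start, self.r_end) >= self.arc_radius:
            raise InvalidParameterError("band radius must stay below the arc radius")
        if abs(np.cos(self.electrode_alpha_c)) < 1e-12:
            raise InvalidGeometryError("electrode elevation α_c = ±π/2 is singular")
        if self.motion is None:
            object.__setattr__(
                self, "motion", ConoidExponentialMotion(path_length=self.path_length)
            )

    def band_radius_at(self, s: float) -> float:
        """Linearly tapered band radius at arc position ``s``."""
        u = np.clip(s / self.path_length, 0.0, 1.0)
        return float(self.r_start + (self.r_end - self.r_start) * u)


_ARCSIN_SLACK = 1e-12


def conoid_potential(params: ConoidModelParams, t: float) -> float:
    """Single-electrode potential of the conoidal model at time ``t``.

    A composite (periodic trapezoid) quadrature over the band angle θ.  For
    each θ the microregion position is fixed by the sub-expressions
    ``OL² = R² + r² - 2 R r cos θ`` and ``φ = arcsin(r sin θ / OL)``; the
    electrode distance ρ follows the spherical relation
    ``ρ² = OL² + OQ² - 2 OL OQ cos(φ - φ_c) cos(α_c - α)``.  Dipoles point
    toward the band center; the moment scale is the stated prefactor
    ``|P| δ r(t) α(t) tan α_c``.
    """
    motion = params.motion
    assert motion is not None
    s = motion.position(float(t))
    r = params.band_radius_at(s)
    alpha = s / params.arc_radius
    big_r = params.arc_radius
    n_ang = params.n_angular
    theta = 2.0 * np.pi * np.arange(n_ang) / n_ang

    ol = np.sqrt(big_r ** 2 + r ** 2 - 2.0 * big_r * r * np.cos(theta))
    sin_phi = r * np.sin(theta) / np.maximum(ol, 1e-300)
    if np.any(np.abs(sin_phi) > 1.0 + _ARCSIN_SLACK):
        raise NumericError("arcsine argument left [-1, 1] in the conoid model")
    phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))

    oq = params.electrode_oq
    rho_sq = (ol ** 2 + oq ** 2
              - 2.0 * ol * oq * np.cos(phi - params.electrode_phi_c)
              * np.cos(params.electrode_alpha_c - alpha))
    rho = np.sqrt(np.maximum(rho_sq, 1e-300))

    # Cartesian assembly consistent with the sub-expressions above: the band
    # plane contains the origin and tilts with α(t).
    axial = big_r - r * np.cos(theta)          # component along the O->O'' axis
    band_points = np.column_stack((
        r * np.sin(theta),
        axial * np.cos(alpha),
        axial * np.sin(alpha),
    ))
    center = big_r * np.array([0.0, np.cos(alpha), np.sin(alpha)])
    inward = (center - band_points) / r        # unit: toward the band center
    electrode = conoid_to_cartesian(oq, params.electrode_phi_c,
                                    params.electrode_alpha_c)
    dots = np.einsum("ij,ij->i", inward, electrode - band_points)

    integral = float(np.sum(dots / rho ** 3)) * (2.0 * np.pi / n_ang)
    if not np.isfinite(integral):
        raise NumericError("conoid-model quadrature did not converge")
    prefactor = (params.moment_density * params.band_width * r * alpha
                 * np.tan(params.electrode_alpha_c))
    return prefactor * integral / (4.0 * np.pi * params.permittivity)


def conoid_reference_signal(scenario: "Scenario", times,
                            n_angular: int | None = None,
                            update_rate: float | None = None) -> EGGSignal:
    """Differential EGG of the analytic conoidal model on a scenario.

    ``update_rate`` (Hz) is the temporal resolution at which the band angles
    α(t), φ(t, θ) are refreshed — the conventional model's "centerline
    sampling rate".  When set below the output rate, band states are held
    between updates (zero-order hold), reproducing the coarse-update regime
    of the conventional method.
    """
    motion = scenario.motion
    if not isinstance(motion, ConoidExponentialMotion):
        raise InvalidParameterError(
            "conoid reference model requires a conoid_exponential motion law"
        )
    times = np.asarray(times, dtype=float)
    eval_times = times
    if update_rate is not None:
        if update_rate <= 0.0:
            raise InvalidParameterError("update rate must be positive")
        eval_times = np.floor(times * update_rate) / update_rate
    radii = scenario.centerline.radii
    arc = scenario.centerline.total_length
    params = ConoidModelParams(
        arc_radius=float(np.linalg.norm(scenario.centerline.points[0])),
        r_start=float(radii[0]),
        r_end=float(radii[-1]),
        path_length=arc,
        band_width=scenario.band_width if scenario.band_width
        else arc / (scenario.centerline.n_points - 1),
        moment_density=scenario.constants.moment_density,
        permittivity=scenario.constants.permittivity,
        electrode_oq=1.0, electrode_phi_c=0.0, electrode_alpha_c=0.0,
        motion=motion,
        n_angular=n_angular if n_angular is not None else 720,
    )
    signals = {}
    for name, pos in (("v1", scenario.measurement), ("v0", scenario.reference)):
        oq, phi_c, alpha_c = cartesian_to_conoid(pos)
        p = replace(params, electrode_oq=oq, electrode_phi_c=phi_c,
                    electrode_alpha_c=alpha_c)
        signals[name] = np.array([conoid_potential(p, float(t))
                                  for t in eval_times])
    sr = 1.0 / float(times[1] - times[0]) if times.size > 1 else scenario.sampling_rate
    return EGGSignal(times=times, v1=signals["v1"], v0=signals["v0"],
                     sampling_rate=sr)


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

def compare_models(proposed, reference) -> dict[str, float]:
    """Agreement report between two time-aligned differential signals.

    Returns the zero-lag normalised cross-correlation (Pearson, mean
    removed), the peak-to-peak amplitude ratio (proposed / reference), the
    least-squares amplitude scale mapping the reference onto the proposed
    signal, and the maximum absolute residual after that scaling.
    """
    a = proposed.v if isinstance(proposed, EGGSignal) else np.asarray(
        proposed, dtype=float)
    b = reference.v if isinstance(reference, EGGSignal) else np.asarray(
        reference, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ComparisonError(
            f"signals are not alignable: shapes {a.shape} vs {b.shape}"
        )
    da, db = a - a.mean(), b - b.mean()
    norm = float(np.linalg.norm(da) * np.linalg.norm(db))
    correlation = float(np.dot(da, db) / norm) if norm > 0.0 else 1.0
    ptp_b = float(np.ptp(b))
    amplitude_ratio = float(np.ptp(a) / ptp_b) if ptp_b > 0.0 else np.inf
    denom = float(np.dot(b, b))
    scale = float(np.dot(b, a) / denom) if denom > 0.0 else 0.0
    residual = float(np.max(np.abs(a - scale * b)))
    return {
        "correlation": correlation,
        "amplitude_ratio": amplitude_ratio,
        "scale": scale,
        "max_residual": residual,
    }
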