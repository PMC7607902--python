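"""Electric potential of the dipole-laden annular band.

Every active microregion carries a point dipole at its center.  The dipole
moment is the moment line density ``|P|`` (C/cm) times the quad's
circumferential chord, directed along the microregion normal — by default
*inward*, toward the centerline, which is the depolarization-front convention
under which the differential EGG rises as the band approaches the measurement
electrode.  The potential of one dipole at an electrode ``E`` is

    V = (1 / 4πε) · P · ρ / |ρ|³,       ρ = E - center,

in an unbounded homogeneous medium of permittivity ``ε`` (C²/(N·cm²)); the
band potential is the plain superposition over all quads of all active rings.
Summing ``P·ρ/ρ³`` rather than ``(P/ΔS)·ρ·ΔS/ρ³`` with a second explicit
area factor is the only dimensionally consistent composition of a dipole
*density* with the microregion area.

The differential EGG sample is ``V = V1 - V0`` between the measurement and
reference electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .dynamics import position_to_active_rings
from .errors import DegenerateQuadWarning, InvalidParameterError, SingularityError
from .geometry import Microregion, TubeMesh

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

__all__ = [
    "Electrode",
    "DipoleConstants",
    "EGGSignal",
    "microregion_potential",
    "band_potential",
    "simulate",
    "MIN_ELECTRODE_DISTANCE",
]

#: electrodes closer than this (cm) to any active dipole are rejected
MIN_ELECTRODE_DISTANCE = 1e-6


@dataclass(frozen=True)
class Electrode:
    """A measurement point in the volume conductor."""

    position: np.ndarray          # (3,) cm
    role: str = "measurement"     # "measurement" | "reference"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidParameterError("electrode position must be a finite 3-vector")
        if self.role not in ("measurement", "reference"):
            raise InvalidParameterError(f"unknown electrode role {self.role!r}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class DipoleConstants:
    """Physical constants of the dipole layer.

    ``moment_density`` is the dipole moment per unit circumferential length
    |P| in C/cm; ``permittivity`` is ε in C²/(N·cm²); ``orientation`` selects
    whether dipoles point toward ("inward") or away from ("outward") the
    centerline.
    """

    moment_density: float
    permittivity: float
    orientation: str = "inward"

    def __post_init__(self) -> None:
        if self.moment_density <= 0.0 or self.permittivity <= 0.0:
            raise InvalidParameterError("|P| and ε must be positive")
        if self.orientation not in ("inward", "outward"):
            raise InvalidParameterError(
                f"orientation must be 'inward' or 'outward', got {self.orientation!r}"
            )

    @property
    def sign(self) -> float:
        return -1.0 if self.orientation == "inward" else 1.0


@dataclass(frozen=True)
class EGGSignal:
    """Uniformly sampled differential EGG record."""

    times: np.ndarray          # s
    v1: np.ndarray             # potential at the measurement electrode
    v0: np.ndarray             # potential at the reference electrode
    sampling_rate: float       # Hz

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        v1 = np.asarray(self.v1, dtype=float)
        v0 = np.asarray(self.v0, dtype=float)
        if not (times.shape == v1.shape == v0.shape) or times.ndim != 1:
            raise InvalidParameterError("signal columns must be equal-length 1D")
        if self.sampling_rate <= 0.0:
            raise InvalidParameterError("sampling rate must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "v0", v0)

    @property
    def v(self) -> np.ndarray:
        """Differential potential ``V = V1 - V0``."""
        return self.v1 - self.v0

    def __len__(self) -> int:
        return self.times.size


def microregion_potential(region: Microregion, moment: np.ndarray,
                          electrode: Electrode | np.ndarray,
                          permittivity: float) -> float:
    """Potential contribution ``(1/4πε) P·ρ/|ρ|³`` of a single microregion.

    ``moment`` is the full dipole moment vector of the region (C·cm scale);
    ``ρ`` runs from the region center to the electrode.
    """
    if permittivity <= 0.0:
        raise InvalidParameterError("permittivity must be positive")
    pos = electrode.position if isinstance(electrode, Electrode) else np.asarray(
        electrode, dtype=float)
    rho = pos - region.center
    dist = float(np.linalg.norm(rho))
    if dist < MIN_ELECTRODE_DISTANCE:
        raise SingularityError(
            f"electrode coincides with microregion (m={region.m}, n={region.n})"
        )
    return float(np.dot(np.asarray(moment, dtype=float), rho)
                 / (4.0 * np.pi * permittivity * dist ** 3))


def band_potential(mesh: TubeMesh, ring_indices: np.ndarray,
                   constants: DipoleConstants,
                   electrode: Electrode | np.ndarray) -> float:
    """Potential at one electrode from all quads of the active rings.

    Each quad's moment magnitude is ``|P| ×`` its circumferential chord, so a
    full ring at radius r carries total moment ``|P| · 2πr`` in the fine-mesh
    limit.  Degenerate (zero-area) quads contribute nothing and emit a
    warning.  An empty active set yields 0.
    """
    pos = electrode.position if isinstance(electrode, Electrode) else np.asarray(
        electrode, dtype=float)
    total = 0.0
    warned = False
    for n in np.asarray(ring_indices, dtype=int):
        geom = mesh.ring_geometry(int(n))
        ok = geom["areas"] > 0.0
        if not warned and not np.all(ok):
            warnings.warn(
                f"ring {int(n)} contains degenerate quads; they carry no dipole",
                DegenerateQuadWarning,
                stacklevel=2,
            )
            warned = True
        normals = geom["outward_normals"][ok]
        centers = geom["centers"][ok]
        chords = geom["chords"][ok]
        rho = pos - centers
        dist = np.linalg.norm(rho, axis=1)
        if dist.size and float(dist.min()) < MIN_ELECTRODE_DISTANCE:
            raise SingularityError(
                f"electrode within {MIN_ELECTRODE_DISTANCE} cm of a dipole "
                f"in ring {int(n)}"
            )
        moments = (constants.sign * constants.moment_density
                   * chords[:, None] * normals)
        total += float(np.sum(np.einsum("ij,ij->i", moments, rho) / dist ** 3))
    return total / (4.0 * np.pi * constants.permittivity)


def simulate(scenario: "Scenario", *, duration: float | None = None,
             sampling_rate: float | None = None,
             mesh: TubeMesh | None = None,
             circle_samples: int | None = None) -> EGGSignal:
    """Run a scenario: move the band along the tube and record ``V1 - V0``.

    Samples are taken at fixed instants ``k / SR`` for ``k = 0 … duration·SR``
    (inclusive endpoint); the band state is evaluated exactly at each instant
    since the motion laws are closed-form.  The simulation is deterministic.
    """
    sr = float(sampling_rate if sampling_rate is not None else scenario.sampling_rate)
    dur = float(duration if duration is not None else scenario.duration)
    if sr <= 0.0 or dur <= 0.0:
        raise InvalidParameterError("sampling rate and duration must be positive")
    if mesh is None:
        mesh = scenario.build_mesh(circle_samples=circle_samples)
    band_width = scenario.effective_band_width(mesh)
    n_samples = int(round(dur * sr)) + 1
    times = np.arange(n_samples) / sr
    v1 = np.empty(n_samples)
    v0 = np.empty(n_samples)
    for k, t in enumerate(times):
        try:
            s = scenario.motion.position(float(t))
            rings = position_to_active_rings(mesh, s, band_width)
            v1[k] = band_potential(mesh, rings, scenario.constants,
                                   scenario.measurement)
            v0[k] = band_potential(mesh, rings, scenario.constants,
                                   scenario.reference)
        except SingularityError as exc:
            raise SingularityError(f"at sample {k} (t = {t:.3f} s): {exc}") from exc
    return EGGSignal(times=times, v1=v1, v0=v0, sampling_rate=sr)
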