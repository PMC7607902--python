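"""File I/O: signal CSV, centerline CSV, Wavefront OBJ, scenario YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import make_motion
from .errors import InvalidParameterError
from .field import DipoleConstants, EGGSignal
from .geometry import Centerline, TubeMesh
from .scenarios import Scenario, get_scenario

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_metadata_json",
    "write_centerline_csv",
    "read_centerline_csv",
    "export_obj",
    "read_obj",
    "load_scenario_file",
]


# --------------------------------------------------------------------------
# signals
# --------------------------------------------------------------------------

def write_signal_csv(signal: EGGSignal, path) -> None:
    """Write ``time_s,V1,V0,V`` with a header row, LF endings, '.' decimals."""
    rows = np.column_stack((signal.times, signal.v1, signal.v0, signal.v))
    with open(path, "w", newline="\n") as fh:
        fh.write("time_s,V1,V0,V\n")
        for row in rows:
            fh.write(",".join(format(x, ".12g") for x in row) + "\n")


def read_signal_csv(path) -> EGGSignal:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    times = data[:, 0]
    sr = 1.0 / float(times[1] - times[0]) if times.size > 1 else 1.0
    return EGGSignal(times=times, v1=data[:, 1], v0=data[:, 2], sampling_rate=sr)


def write_metadata_json(path, scenario: Scenario, *, extra: dict | None = None) -> None:
    """Sidecar metadata describing the run (parameters and unit notes)."""
    from . import __version__

    meta = {
        "software": {"name": "eggsim", "version": __version__},
        "scenario": {
            "name": scenario.name,
            "n_circles": scenario.centerline.n_points,
            "circle_samples": scenario.circle_samples,
            "total_length_cm": scenario.centerline.total_length,
            "ring_width_cm": scenario.ring_width,
            "band_width_cm": scenario.effective_band_width(),
            "moment_density_C_per_cm": scenario.constants.moment_density,
            "permittivity_C2_per_N_cm2": scenario.constants.permittivity,
            "orientation": scenario.constants.orientation,
            "measurement_electrode_cm": scenario.measurement.tolist(),
            "reference_electrode_cm": scenario.reference.tolist(),
            "sampling_rate_hz": scenario.sampling_rate,
            "duration_s": scenario.duration,
            "motion": type(scenario.motion).__name__,
        },
        "units": "all lengths in centimetres; metre-specified inputs converted",
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# centerlines
# --------------------------------------------------------------------------

def write_centerline_csv(centerline: Centerline, path) -> None:
    """Plain CSV with columns ``x,y,z,r`` (header row, centimetres)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("x,y,z,r\n")
        for p, r in zip(centerline.points, centerline.radii):
            fh.write(",".join(format(v, ".12g") for v in (*p, r)) + "\n")


def read_centerline_csv(path) -> Centerline:
    data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
    if data.shape[1] != 4:
        raise InvalidParameterError("centerline CSV must have columns x,y,z,r")
    return Centerline(data[:, :3], data[:, 3])


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def export_obj(mesh: TubeMesh, path, *, triangulate: bool = False) -> None:
    """Write the tube as Wavefront OBJ.

    Vertices are circle-major (all ``M`` samples of circle 0, then circle 1,
    ...), faces are quads by default — preserving the microregion structure —
    with 1-based indexing and cyclic circumferential wrap.  ``triangulate``
    splits each quad along the diagonal used for the microregion center.
    """
    n, m = mesh.n_circles, mesh.circle_samples
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# eggsim tube mesh: {n} circles x {m} samples (cm)\n")
        for circle in mesh.vertices:
            for v in circle:
                fh.write("v " + " ".join(format(x, ".9g") for x in v) + "\n")
        for ring in range(n - 1):
            base0 = ring * m
            base1 = (ring + 1) * m
            for i in range(m):
                j = (i + 1) % m
                a, b = base0 + i + 1, base0 + j + 1
                c, d = base1 + j + 1, base1 + i + 1
                if triangulate:
                    fh.write(f"f {a} {b} {c}\n")
                    fh.write(f"f {a} {c} {d}\n")
                else:
                    fh.write(f"f {a} {b} {c} {d}\n")


def read_obj(path) -> tuple[np.ndarray, list[list[int]]]:
    """Read vertices and (0-based) faces back from a Wavefront OBJ file."""
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(tok.split("/")[0]) - 1 for tok in parts[1:]])
    return np.asarray(vertices, dtype=float), faces


# --------------------------------------------------------------------------
# scenario files
# --------------------------------------------------------------------------

def load_scenario_file(path) -> Scenario:
    """Load a scenario from YAML (or JSON, a YAML subset).

    Schema::

        name: my-run                  # optional
        scenario: cylinder            # base built-in, with optional
        params: {n_circles: 200}      #   builder overrides
        # or a custom centerline instead of a built-in:
        centerline: {csv: path/to/centerline.csv}
        motion: {law: constant_linear, length: 10.0, freq_cpm: 5.4}
        constants: {moment_density: 4.5e-8, permittivity: 2.65e-8}
        electrodes: {measurement: [0, 0, 4.2], reference: [0, 0, 4.0]}
        circle_samples: 100
        sampling_rate: 10.0
        duration: 60.0
        band_width: 0.011             # cm, optional

    Any top-level key present overrides the base scenario's value.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"scenario file {path} is not a mapping")

    if "scenario" in cfg:
        base = get_scenario(cfg["scenario"], **cfg.get("params", {}))
    elif "centerline" in cfg:
        cl_cfg = cfg["centerline"]
        if "csv" not in cl_cfg:
            raise InvalidParameterError("custom centerline requires a 'csv' key")
        csv_path = Path(cl_cfg["csv"])
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        centerline = read_centerline_csv(csv_path)
        if "motion" not in cfg or "constants" not in cfg or "electrodes" not in cfg:
            raise InvalidParameterError(
                "custom-centerline scenarios need motion, constants and electrodes"
            )
        motion_cfg = dict(cfg["motion"])
        motion = make_motion(motion_cfg.pop("law"), **motion_cfg)
        base = Scenario(
            name=cfg.get("name", csv_path.stem),
            centerline=centerline,
            circle_samples=int(cfg.get("circle_samples", 100)),
            constants=DipoleConstants(**cfg["constants"]),
            measurement=np.asarray(cfg["electrodes"]["measurement"], dtype=float),
            reference=np.asarray(cfg["electrodes"]["reference"], dtype=float),
            motion=motion,
        )
    else:
        raise InvalidParameterError(
            "scenario file needs either a 'scenario' or a 'centerline' key"
        )

    overrides = {}
    if "name" in cfg:
        overrides["name"] = cfg["name"]
    for key in ("circle_samples", "sampling_rate", "duration", "band_width"):
        if key in cfg:
            overrides[key] = cfg[key]
    if "constants" in cfg and "scenario" in cfg:
        overrides["constants"] = DipoleConstants(**cfg["constants"])
    if "electrodes" in cfg and "scenario" in cfg:
        overrides["measurement"] = np.asarray(
            cfg["electrodes"]["measurement"], dtype=float)
        overrides["reference"] = np.asarray(
            cfg["electrodes"]["reference"], dtype=float)
    if "motion" in cfg and "scenario" in cfg:
        motion_cfg = dict(cfg["motion"])
        overrides["motion"] = make_motion(motion_cfg.pop("law"), **motion_cfg)
    return base.with_overrides(**overrides) if overrides else base
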