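"""Shared fixtures: benchmark scenarios, meshes and simulated signals.

Session scope keeps the expensive objects (the 910x100 cylinder mesh and its
simulated waveforms) built once for the whole run.
"""

import numpy as np
import pytest

import eggsim as eg


@pytest.fixture(scope="session")
def cylinder_scenario():
    return eg.get_scenario("cylinder")


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_scenario):
    return cylinder_scenario.build_mesh()


@pytest.fixture(scope="session")
def cylinder_cycle_signal(cylinder_scenario, cylinder_mesh):
    """One full band-traversal cycle of the cylinder benchmark at 10 Hz."""
    return eg.simulate(cylinder_scenario,
                       duration=cylinder_scenario.motion.period,
                       mesh=cylinder_mesh)


@pytest.fixture(scope="session")
def conoid_scenario():
    return eg.get_scenario("conoid")


@pytest.fixture(scope="session")
def pseudocolon_scenario():
    return eg.get_scenario("pseudocolon")


@pytest.fixture(scope="session")
def helix_centerline():
    """A generic 3D test curve: one helix turn with varying radius."""
    t = np.linspace(0.0, 2.0 * np.pi, 50)
    points = np.column_stack((3.0 * np.cos(t), 3.0 * np.sin(t), 1.5 * t))
    radii = 0.8 + 0.3 * np.sin(3.0 * t)
    return eg.Centerline(points, radii)


@pytest.fixture(scope="session")
def helix_mesh(helix_centerline):
    return eg.build_tube_mesh(helix_centerline, 32)
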