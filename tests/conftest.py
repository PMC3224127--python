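"""Shared fixtures: small meshes, grids, and phantom realizations.

The expensive full engine runs live in module-scoped fixtures inside
test_acceptance.py so the rest of the suite stays fast.
"""

import logging

import numpy as np
import pytest

from multiseg import (
    RunConfig,
    ScalarVolume,
    build_simplex_sphere,
    generate,
    run,
)
from multiseg.phantom import PhantomSpec, default_tube

logging.getLogger("multiseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def unit_sphere0():
    """Dodecahedron: dual of the icosahedron, all 20 vertices equivalent."""
    return build_simplex_sphere((0.0, 0.0, 0.0), 1.0, 0)


@pytest.fixture(scope="session")
def unit_sphere1():
    return build_simplex_sphere((0.0, 0.0, 0.0), 1.0, 1)


@pytest.fixture(scope="session")
def unit_sphere2():
    return build_simplex_sphere((0.0, 0.0, 0.0), 1.0, 2)


@pytest.fixture()
def grid20():
    """Isotropic 20^3 unit grid."""
    return ScalarVolume(np.zeros((20, 20, 20)), [1, 1, 1], [0, 0, 0])


@pytest.fixture(scope="session")
def phantom4():
    """The standard 4-touching-ellipsoid tube phantom (fixed seed)."""
    spec = default_tube(4)
    volume, truths, seeds, training = generate(spec)
    return spec, volume, truths, seeds, training


@pytest.fixture(scope="session")
def single_object_run():
    """One full engine run on a single-ellipsoid phantom, with its inputs."""
    spec = PhantomSpec(
        centers=np.array([[31.5, 31.5, 31.5]]),
        semi_axes=np.array([[8.0, 8.0, 10.0]]),
    )
    volume, truths, seeds, training = generate(spec)
    config = RunConfig(seeds=seeds)
    masks = run(volume, config, training)
    return {
        "spec": spec,
        "volume": volume,
        "truths": truths,
        "seeds": seeds,
        "training": training,
        "config": config,
        "masks": masks,
        "report": run.last_report,
        "states": run.last_states,
    }
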