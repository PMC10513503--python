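"""Shared fixtures: small phantoms and pre-assembled BEM systems.

Heavy objects (assembled systems, transfer stacks) are session-scoped so the
whole suite pays for them once.
"""

import numpy as np
import pytest
import trimesh as _trimesh

from ecgidipole import (
    PhantomSpec,
    TriMesh,
    VolumeConductor,
    assemble_bem,
    build_transfer_stack,
    make_phantom,
    place_electrode_strips,
)


@pytest.fixture(scope="session")
def icosa():
    """Regular icosahedron mesh (12 vertices, 20 triangles)."""
    ico = _trimesh.creation.icosahedron()
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "icosa").validate()


@pytest.fixture(scope="session")
def unit_cube():
    """Unit cube surface (12 triangles, volume 1), corner at origin."""
    box = _trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    v = np.asarray(box.vertices) + 0.5
    return TriMesh(v, np.asarray(box.faces), "cube").validate()


@pytest.fixture(scope="session")
def sphere_conductor():
    """Homogeneous sphere conductor, radius 100 mm, refinement 3, 16 electrodes."""
    R, sigma = 100.0, 0.2
    tm = _trimesh.creation.icosphere(subdivisions=3, radius=R)
    torso = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "sphere").validate()
    montage = place_electrode_strips(torso, 4, 4)
    vc = VolumeConductor((torso,), [sigma], [0.0], montage)
    return vc, R, sigma


@pytest.fixture(scope="session")
def sphere_system(sphere_conductor):
    vc, R, sigma = sphere_conductor
    return assemble_bem(vc), R, sigma


@pytest.fixture(scope="session")
def small_phantom():
    """Reference homogeneous phantom: 128 electrodes, 162 candidate vertices."""
    spec = PhantomSpec(snr_db=np.inf, true_vertex=7)
    vc, heart = make_phantom(spec)
    system = assemble_bem(vc)
    stack = build_transfer_stack(system, heart)
    return spec, vc, heart, system, stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230907)
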