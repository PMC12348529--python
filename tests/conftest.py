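"""Shared fixtures: small meshes and canonical material parameters."""

from __future__ import annotations

import numpy as np
import pytest

from cogsim.constitutive import TABLE_TISSUE_OGDEN, THREAD_LINEAR_ELASTIC
from cogsim.mesh import structured_box
from cogsim.synthetic import CanalGeometrySpec, generate_canal_geometry


@pytest.fixture(scope="session")
def tissue():
    """Three-term vagina/uterus Ogden parameter set (solver convention)."""
    return TABLE_TISSUE_OGDEN


@pytest.fixture(scope="session")
def thread_material():
    return THREAD_LINEAR_ELASTIC


def make_pinned_bar(lx=2.0, ly=10.0, lz=2.0, nx=1, ny=2, nz=1):
    """Bar with roller end faces plus minimal rigid-mode pins.

    "ymin"/"ymax" carry the axial constraint; "pin0" (x, z) and
    "pin1" (z) remove the in-plane rigid modes so a uniaxial stress
    state stays homogeneous.
    """
    mesh = structured_box(lx, ly, lz, nx=nx, ny=ny, nz=nz)
    n = mesh.nodes
    i0 = int(np.argmin(np.linalg.norm(n - [-lx / 2, 0, -lz / 2], axis=1)))
    i1 = int(np.argmin(np.linalg.norm(n - [lx / 2, 0, -lz / 2], axis=1)))
    mesh.add_node_set("pin0", [i0])
    mesh.add_node_set("pin1", [i1])
    return mesh


@pytest.fixture(scope="session")
def pinned_bar():
    return make_pinned_bar()


@pytest.fixture(scope="session")
def small_canal():
    """Coarse synthetic canal used by the scenario ordering tests."""
    spec = CanalGeometrySpec(
        length=40.0, inner_radius=10.0, wall_thickness=2.5, mesh_edge=8.0
    )
    return spec, generate_canal_geometry(spec)
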