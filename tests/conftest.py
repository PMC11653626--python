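"""Shared fixtures: small synthetic cases reused across the suite."""

import numpy as np
import pytest

from aortamech import (MembraneModel, SurfaceMesh, SyntheticCaseSpec,
                       gen_fusiform_aneurysm, gen_pulsating_cylinder)
from aortamech.synthetic import MMHG_TO_MPA

P120 = 120.0 * MMHG_TO_MPA


@pytest.fixture(scope="session")
def cylinder_case():
    spec = SyntheticCaseSpec(shape="cylinder", R0=10.0, length=80.0,
                             n_circ=48, n_axial=40, n_phases=7,
                             peak_hoop_stretch=1.05)
    return gen_pulsating_cylinder(spec)


@pytest.fixture(scope="session")
def fusiform_case():
    spec = SyntheticCaseSpec(shape="fusiform", R0=10.0, bump_amplitude=10.0,
                             bump_center_z=60.0, bump_width=15.0,
                             length=120.0, n_circ=48, n_axial=40)
    return gen_fusiform_aneurysm(spec)


@pytest.fixture(scope="session")
def sphere_mesh():
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return SurfaceMesh(np.asarray(ico.vertices, dtype=float),
                       np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def cylinder_tension(cylinder_case):
    """Linear tension solve on the open clamped reference cylinder."""
    from aortamech import solve_membrane_tension

    seq, _ = cylinder_case
    model = MembraneModel(seq.mesh, h=0.01)
    return solve_membrane_tension(model, P120, bc="clamp_rings")
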