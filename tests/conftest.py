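import numpy as np
import pytest

from trunkflow import geometry, hydraulics, units


@pytest.fixture(scope="session")
def trunk12():
    """Default 12-Se trunk network (caudally narrowed DA)."""
    return geometry.build_trunk(12)


@pytest.fixture(scope="session")
def uniform12():
    """Exact uniform ladder: constant DA radius."""
    return geometry.build_trunk(12, geometry.default_geometry_table(12, uniform=True))


@pytest.fixture(scope="session")
def printed_kappas():
    """Conductances of the default uniform geometry under whole blood."""
    k1 = 1.0 / hydraulics.poiseuille_resistance(
        geometry.DA_SEGMENT_LENGTH, geometry.DA_RADIUS_HEAD, units.MU_WHOLE_BLOOD
    )
    k2 = 1.0 / hydraulics.poiseuille_resistance(
        geometry.SE_LENGTH, geometry.SE_RADIUS, units.MU_WHOLE_BLOOD
    )
    return k1, k2


def se_flows(t, state):
    idx = [k for k, v in enumerate(t.vessels) if v.kind == geometry.VesselKind.SE]
    return state.flows[idx]


@pytest.fixture(scope="session")
def whole_blood_solve(trunk12):
    """No-occlusion whole-blood Kirchhoff solve on the default network."""
    model = hydraulics.ResistanceModel(
        trunk12, hydraulics.OcclusionParams(), mode="continuum_whole_blood"
    )
    state = hydraulics.solve_flows(
        trunk12, model.total(np.zeros(len(trunk12.vessels))), 1.0
    )
    return model, state
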