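from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_ligand():
    from dockprof.synthetic import TOY_LIGANDS

    return TOY_LIGANDS["toy_glucosinolate"]()


def make_pose(coords, pose_id="p0", frame_id="frame_000", ligand=None):
    """LigandPose with the toy-glucosinolate topology and given coordinates."""
    from dockprof.synthetic import TOY_LIGANDS, _make_pose

    lig = ligand or TOY_LIGANDS["toy_glucosinolate"]()
    pose = _make_pose(lig, np.asarray(coords, float), pose_id, frame_id, 1, -9.0)
    pose.pose_id = pose_id
    return pose


@pytest.fixture(scope="session")
def two_cluster_data(tmp_path_factory):
    """A small generated two-cluster scenario, written to disk once."""
    from dockprof.synthetic import generate_scenario, two_cluster_spec

    out = tmp_path_factory.mktemp("scenario_k2")
    return generate_scenario(two_cluster_spec(seed=11), out)


@pytest.fixture(scope="session")
def standard_data():
    """The in-memory benchmark scenario (3 clusters, planted contact per type)."""
    from dockprof.synthetic import generate_scenario, standard_scenario_spec

    return generate_scenario(standard_scenario_spec(seed=7))
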