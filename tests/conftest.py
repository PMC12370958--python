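import numpy as np
import pandas as pd
import pytest

from pdpose.pose import NodeId, PoseSequence
from pdpose.simulate import (CohortSpec, GroupSpec, generate_cohort,
                             generate_session, preset)
from pdpose.kinematics import featurize_session


def make_pose(n_frames: int = 10, fs: float = 30.0, **nodes) -> PoseSequence:
    """Build a PoseSequence with given per-node trajectories.

    Node kwargs accept a constant 3-vector or an (n_frames, 3) array;
    unspecified nodes sit at distinct fixed offsets so no geometry is
    accidentally degenerate.
    """
    coords = np.zeros((n_frames, 9, 3))
    for node in NodeId:
        coords[:, int(node), 0] = 0.1 * int(node)  # default spread along x
    for name, val in nodes.items():
        val = np.asarray(val, float)
        coords[:, int(NodeId[name]), :] = val
    return PoseSequence(coords, fs=fs)


@pytest.fixture(scope="session")
def control_session():
    return generate_session(preset("control"), 600.0, 30.0, seed=101,
                            mouse_id="ct_0", group="control")


@pytest.fixture(scope="session")
def pd_session():
    return generate_session(preset("pd_severe"), 600.0, 30.0, seed=202,
                            mouse_id="pd_0", group="pd_severe")


@pytest.fixture(scope="session")
def cohort():
    """10 control + 10 severe-PD mice, 6-min sessions (desk-scale cohort)."""
    spec = CohortSpec(
        groups=(GroupSpec("control", preset("control"), 10),
                GroupSpec("pd_severe", preset("pd_severe"), 10)),
        weeks=(0,), seed=11, duration_s=360.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    return pd.concat([featurize_session(seq) for seq, _ in cohort],
                     ignore_index=True)
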