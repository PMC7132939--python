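import numpy as np
import pandas as pd
import pytest

from mvbkit.geometry import Box3D, StackGeometry
from mvbkit.synthetic import ProcessSpec, generate_point_pattern


@pytest.fixture
def frame_window() -> Box3D:
    """A cube with the study's mean counting-frame volume (277.23 μm³)."""
    return Box3D.cube(277.23)


@pytest.fixture
def csr_pattern(frame_window):
    return generate_point_pattern(ProcessSpec.csr(0.21), frame_window, seed=7)


def make_catalog(positions, volumes, stack_id=0, layer="I", **flags):
    """Minimal catalog table from explicit positions/volumes."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pos)
    vols = np.broadcast_to(np.asarray(volumes, dtype=float), (n,))
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "volume_um3": vols,
            "layer": layer,
            "compartment": "dendrite",
            "docked": flags.get("docked", False),
            "tubules": flags.get("tubules", False),
            "clathrin": flags.get("clathrin", False),
            "stack_id": stack_id,
        }
    )
    return df


@pytest.fixture
def small_geometry():
    return StackGeometry(shape=(64, 64, 64), voxel_size_nm=(20.0, 20.0, 20.0))
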