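import numpy as np
import pytest

import pldstim as p


@pytest.fixture(scope="session")
def walker():
    """Deterministic 3 s / 120 Hz walking clip."""
    return p.make_walker(p.GaitParams(seed=42))


@pytest.fixture(scope="session")
def marker_walker(walker):
    """41-marker expansion of the walker."""
    return p.expand_to_markers(walker)


@pytest.fixture(scope="session")
def catalog(tmp_path_factory):
    """Synthetic action catalog with clips on disk."""
    root = tmp_path_factory.mktemp("catalog")
    p.make_catalog_fixture(seed=7, out_dir=root)
    return p.ActionCatalog.from_manifest(root / "catalog.json")


@pytest.fixture()
def static_clip():
    """A motionless standing agent (120 frames at 60 Hz)."""
    pose = p.neutral_pose()
    return p.JointClip(positions=np.repeat(pose[None], 120, axis=0), rate=60.0)
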