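import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from refassess import synthdata


@pytest.fixture(scope="session")
def helix_native():
    return synthdata.generate_native(11, 24, "helix", id="helix24")


@pytest.fixture(scope="session")
def small_round():
    """A 2-target round with 4 groups, used by orchestration tests."""
    profiles = [
        synthdata.GroupProfile("good", 0.4, 0.05, 0.05, 1.0),
        synthdata.GroupProfile("flat", 0.0, 0.0, 0.0, 1.0),
        synthdata.GroupProfile("bad", -0.2, 0.05, 0.05, 0.5),
        synthdata.GroupProfile("wild", 0.1, 0.2, 0.5, 0.2, type="server"),
    ]
    return synthdata.generate_round(
        seed=5, n_targets=2, profiles=profiles, n_res_range=(20, 26), p_missing=0.0
    )
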