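import numpy as np
import pytest

from combnet.network import ClusterAssignment
from combnet.response import RawScreen
from combnet.synthetic import ScreenSpec, simulate_screen


@pytest.fixture
def small_raw():
    """4 samples (3 patient, 1 healthy) x 3 drugs, no missing cells."""
    return RawScreen(
        values=np.array(
            [
                [2.0, 4.0, 6.0],
                [3.0, 5.0, 1.0],
                [6.0, 2.0, 4.0],
                [1.0, 1.5, 2.5],
            ]
        ),
        sample_ids=["s1", "s2", "s3", "h1"],
        drug_ids=["dA", "dB", "dC"],
        sample_class=["patient", "patient", "patient", "healthy"],
    )


@pytest.fixture
def two_cluster_labels():
    return {f"D{i:03d}": 1 if i < 25 else 2 for i in range(50)}


@pytest.fixture
def two_cluster_assignment(two_cluster_labels):
    return ClusterAssignment(labels=two_cluster_labels, modularity=0.5)


@pytest.fixture
def default_screen():
    """Planted two-cluster screen at the default study conditions."""
    return simulate_screen(ScreenSpec(seed=0))
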