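import numpy as np
import pytest

from planxai import CriteriaTable, PolicyValueNet, generate_case
from planxai.phantom import PhantomCase, TPPVector


@pytest.fixture(scope="session")
def small_case():
    return generate_case(seed=1, overlap_level=0.2, size="small")


@pytest.fixture(scope="session")
def criteria():
    return CriteriaTable.default()


@pytest.fixture(scope="session")
def tiny_net():
    """4-hidden-unit network over a 7-value input, for oracle comparisons."""
    return PolicyValueNet.init(3, input_dim=7, dense=5, hidden=4, n_actions=6)


@pytest.fixture(scope="session")
def default_net():
    return PolicyValueNet.init(0)


@pytest.fixture
def identity_case():
    """5 voxels, identity dose matrix, all voxels PTV: the analytic case
    where the optimum puts exactly the prescription dose on every voxel."""
    n = 5
    return PhantomCase(
        case_id="identity", grid_shape=(1, n),
        structure_masks={"PTV": np.arange(n),
                         "BLA": np.empty(0, dtype=int),
                         "REC": np.empty(0, dtype=int)},
        dose_matrix=np.eye(n), prescription_dose=10.0, seed=0)


def ptv_only_tpps():
    return TPPVector(np.array([1.0, 0.05, 0.05, 1.0, 0.85, 0.85,
                               0.5, 0.5, 0.5]))
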