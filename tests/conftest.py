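import numpy as np
import pytest

from stemvaf import build_params
from stemvaf.simulator import Genealogy


@pytest.fixture
def hsc_like_params():
    """Desk-scale version of the hematopoietic reference configuration."""
    return build_params(NM=1000, tM=5.0, NH=50, lam=5.0, p=0.4, mu=1.2)


@pytest.fixture
def tiny_genealogy():
    """Hand-built N=4 population with one variant shared by two cells.

    Founder 0 splits into 1 and 2; the branch into node 1 carries one
    mutation.  Nodes 3,4 (children of 1) are the carriers; 5,6 (children
    of 2) are not.
    """
    return Genealogy(
        parent=np.array([-1, 0, 0, 1, 1, 2, 2]),
        nmut=np.array([0, 1, 0, 0, 0, 0, 0]),
        birth_time=np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0]),
        alive=np.array([3, 4, 5, 6]),
        t=3.0,
        params=build_params(NM=4, tM=1.0, mu=1.0),
    )


@pytest.fixture
def chain_genealogy():
    """Single surviving lineage with ancestral branch counts (3, 1, 0, 2)."""
    return Genealogy(
        parent=np.array([-1, 0, 1, 2, 3]),
        nmut=np.array([0, 3, 1, 0, 2]),
        birth_time=np.arange(5.0),
        alive=np.array([4]),
        t=4.0,
        params=build_params(NM=2, tM=1.0, mu=1.0),
    )
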