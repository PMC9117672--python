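import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from montane import PaleoCurve, Tree


@pytest.fixture
def tree3():
    """The worked three-tip tree: ((A:1,B:1):1,C:2)."""
    return Tree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree4():
    return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def flat_curve():
    return PaleoCurve(ages=np.array([0.0, 45.0]), values=np.array([0.0, 0.0]))


@pytest.fixture
def ramp_curve():
    """Linear 'cooling toward the present' proxy on [0, 45] Ma."""
    return PaleoCurve(ages=np.array([0.0, 45.0]), values=np.array([0.0, 9.0]))
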