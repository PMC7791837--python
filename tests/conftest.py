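import numpy as np
import pytest

from grnrewire.io import read_tree
from grnrewire.motifs import PSSM
from grnrewire.simulate import default_tree


@pytest.fixture
def ladder_tree():
    return default_tree()


@pytest.fixture
def sharp_pssm():
    """Width-10, high-information motif with a fixed consensus."""
    consensus = "CGTTAATTAC"
    counts = np.zeros((4, 10))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 1000.0
    return PSSM("TF_sharp", counts, background=[0.3, 0.2, 0.2, 0.3])


@pytest.fixture
def smooth_pssm():
    """Width-8 motif with a graded column profile (many score atoms)."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 30, (4, 8)).astype(float)
    return PSSM("TF_smooth", counts, background=[0.3, 0.2, 0.2, 0.3])


def balanced_newick(depth: int, branch: float = 1.0, prefix: str = "t") -> str:
    """Newick for a fully balanced binary tree with 2**depth tips."""
    counter = [0]

    def build(d):
        if d == 0:
            counter[0] += 1
            return f"{prefix}{counter[0]}:{branch}"
        return f"({build(d-1)},{build(d-1)}):{branch}"

    return build(depth) + ";"


@pytest.fixture
def balanced32_tree():
    return read_tree(balanced_newick(5))
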