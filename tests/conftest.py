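import numpy as np
import pytest

from nterm.constructs import ConstructSequence

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_wt_like_sequence(length: int = 400, seed: int = 20) -> ConstructSequence:
    """A synthetic wild-type-like sequence carrying the residue identities
    the constructs are defined on (K4, R5, H7, A9, R30, A335, G336)."""
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(AA), size=length))
    for index, letter in [(4, "K"), (5, "R"), (7, "H"), (9, "A"),
                          (30, "R"), (335, "A"), (336, "G")]:
        residues[index - 1] = letter
    return ConstructSequence(name="wt_like", residues="".join(residues))


@pytest.fixture
def wt_sequence() -> ConstructSequence:
    return make_wt_like_sequence()
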