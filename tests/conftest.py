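import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

AA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture
def rng():
    return np.random.default_rng(20140402)


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), n))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([c for c in AA if c != out[i]]))
    return "".join(out)


@pytest.fixture
def protein_family(rng):
    """Eight sequences at ~8% divergence from a common 100-aa root."""
    root = random_protein(rng, 100)
    return [(f"Op_me_ta{i:02d}_{i}", mutate(rng, root, 0.08)) for i in range(8)]
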