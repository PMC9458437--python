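import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_hairpin_structure():
    """Synthetic RNAI-like scaffold: three stem-loops with loop lengths
    7, 6 and 7 (sum 20), plus unpaired leaders/spacers."""
    def hairpin(stem, loop):
        return "(" * stem + "." * loop + ")" * stem
    return "." + hairpin(6, 7) + ".." + hairpin(5, 6) + ".." + hairpin(6, 7) + "."
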