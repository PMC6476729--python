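import warnings

import numpy as np
import pytest

from tpshift.sequence import CodingSequence


@pytest.fixture(autouse=True)
def _quiet_degenerate_pair_warnings():
    # repeat toys like {atg}_50 lack one base, so zero pair probabilities
    # are expected and handled; keep test output readable
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="pair probabilities of 0 or 1 encountered"
        )
        yield


@pytest.fixture
def atg50():
    """{atg}_50: perfectly periodic 150-nt repeat, no phase shift."""
    return CodingSequence.from_string("atg" * 50, "atg50")


@pytest.fixture
def atg_tga():
    """{atg}_25{tga}_25: {atg}_50 with one base deleted at position 76."""
    return CodingSequence.from_string("atg" * 25 + "tga" * 25, "atg_tga")


def random_sequence(rng, n, id="rnd"):
    return CodingSequence(id=id, codes=rng.integers(1, 5, size=n).astype(np.int8))


from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")
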