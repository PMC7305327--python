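import numpy as np
import pytest

from ifcascade.crrna_assembly import RepeatSpec
from ifcascade.mismatch_model import PositionMask
from ifcascade.sequence_io import GenomeSequences
from ifcascade.synthetic_data import EXAMPLE_REPEAT


@pytest.fixture
def repeat() -> RepeatSpec:
    return RepeatSpec(EXAMPLE_REPEAT)


@pytest.fixture
def default_mask() -> PositionMask:
    return PositionMask.cascade_default(32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_genome() -> GenomeSequences:
    # 60-bp sequence with a CC-PAM protospacer on each strand
    return GenomeSequences(
        {
            "chrT": "AACCGTGTGTACGTACGTACGTACGTACGTACACACGGTTACGTACGTACGTACGTACGT",
            "chrU": "ACGT" * 15,
        }
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
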