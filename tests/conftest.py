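import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tagsnp import HaplotypeBlock

# 4-pattern x 5-SNP worked example block
ROWS_4x5 = ["00101", "01100", "10000", "11011"]

# 6-pattern x 8-SNP greedy-initialization example block
ROWS_6x8 = [
    "00101001",
    "01100011",
    "10000100",
    "11011011",
    "00111000",
    "10100011",
]


@pytest.fixture
def rows45():
    return list(ROWS_4x5)


@pytest.fixture
def rows68():
    return list(ROWS_6x8)


@pytest.fixture
def block45():
    return HaplotypeBlock.from_strings(ROWS_4x5)


@pytest.fixture
def block68():
    return HaplotypeBlock.from_strings(ROWS_6x8)
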