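import random
import string

import pytest

from rcmtree.io_formats import SequenceRecord


@pytest.fixture
def toy_records():
    return [
        SequenceRecord(id="s1", residues="AAILNAIIANNL", source_length=12),
        SequenceRecord(id="s2", residues="MKVLPWAAILNA", source_length=12),
        SequenceRecord(id="s3", residues="GGSTPYFWHKRD", source_length=12),
    ]


def random_string(rng: random.Random, length: int, alphabet_size: int) -> str:
    symbols = string.ascii_uppercase[:alphabet_size]
    return "".join(rng.choice(symbols) for _ in range(length))
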