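import pytest

from paralog_evol.seqio import Alignment, SequenceRecord


def make_alignment(rows, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    return Alignment([SequenceRecord(i, r) for i, r in zip(ids, rows)])


@pytest.fixture
def tiny_protein_alignment():
    return make_alignment(["MKVA", "MKVA", "MKTA", "M-VA"])


@pytest.fixture
def identical_alignment():
    return make_alignment(["MKVARST"] * 4)
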