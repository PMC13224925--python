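import pytest

from helixtag import NumberedSequence, helix_hairpin, splice_sequence


@pytest.fixture
def receptor():
    """315-residue receptor numbered 2-316, mirroring an A2A-like core."""
    seq = ("MA" * 200)[:315]
    return NumberedSequence(id="A2AR", sequence=seq, first_auth_num=2)


@pytest.fixture
def tag():
    """106-residue tag with an R at tag position 72."""
    seq = list("LK" * 53)
    seq[71] = "R"
    return NumberedSequence(id="BLAC", sequence="".join(seq), first_auth_num=1)


@pytest.fixture
def control_construct(receptor, tag):
    """The span-replacing control: entry 234, exit 245 (deletes 235-244)."""
    return splice_sequence(receptor, tag, entry=234, exit=245)


@pytest.fixture
def passing_hairpin():
    """Hairpin passing every default screen gate, with its manifest row."""
    return helix_hairpin(12, 12, 10.0, 175.0, loop_len=4, n_pad=0, c_pad=0)
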