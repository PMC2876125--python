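import pytest

from tagmux._seq import revcomp
from tagmux.design import AmpliconDesign, SampleSheet, Tag, TagSet, build_sample_sheet


@pytest.fixture
def design() -> AmpliconDesign:
    return AmpliconDesign()


@pytest.fixture
def small_tagsets() -> tuple[TagSet, TagSet]:
    fwd = TagSet([Tag("F1", "ACT", "forward"), Tag("F2", "CAG", "forward")])
    rev = TagSet([Tag("R1", "TGA", "reverse"), Tag("R2", "GTC", "reverse")])
    return fwd, rev


@pytest.fixture
def small_sheet(small_tagsets) -> SampleSheet:
    fwd, rev = small_tagsets
    return build_sample_sheet(
        [("S1", "sp", 2), ("S2", "sp", 2), ("S3", "sp", 2), ("S4", "sp", 2)],
        fwd, rev, (2, 2, 1), pool="A",
    )


def make_read(design: AmpliconDesign, ftag: str, rtag: str, insert: str) -> str:
    """Assemble a well-formed read string in the standard (A) layout."""
    fp = design.forward_primer
    rp = design.reverse_primer.replace("Y", "C")  # one concrete realisation
    return design.key + ftag + fp + insert + revcomp(rp) + revcomp(rtag)


@pytest.fixture
def read_factory(design):
    def _make(ftag: str, rtag: str, insert: str) -> str:
        return make_read(design, ftag, rtag, insert)

    return _make
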