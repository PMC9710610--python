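import numpy as np
import pytest

from screpsim.germline import (
    GermlineReference,
    GermlineSegment,
    JunctionModel,
    RecombinationSettings,
    UsageDistribution,
)


def make_fixture_reference() -> GermlineReference:
    """A tiny hand-written reference: 4 V / 2 D / 3 J heavy segments plus a
    small light locus.  Sequences are short so junction arithmetic and
    enumeration oracles stay checkable by hand."""
    segs = [
        GermlineSegment("IGHV1-1", "IGH", "V", "ATGGCAGCAGCA"),
        GermlineSegment("IGHV1-2", "IGH", "V", "ATGGCCGCCGCC"),
        GermlineSegment("IGHV1-3", "IGH", "V", "ATGGCGGCGGCG"),
        GermlineSegment("IGHV1-4", "IGH", "V", "ATGGCTGCTGCT"),
        GermlineSegment("IGHD1-1", "IGH", "D", "GGGACT"),
        GermlineSegment("IGHD1-2", "IGH", "D", "CCCAGT"),
        GermlineSegment("IGHJ1", "IGH", "J", "TGGCAACAA"),
        GermlineSegment("IGHJ2", "IGH", "J", "TGGCCACCA"),
        GermlineSegment("IGHJ3", "IGH", "J", "TGGCGACGA"),
        GermlineSegment("IGKV1-1", "IGK", "V", "ATGAAAGCAAAA"),
        GermlineSegment("IGKV1-2", "IGK", "V", "ATGAAGGCCAAG"),
        GermlineSegment("IGKV1-3", "IGK", "V", "ATGAACGCGAAC"),
        GermlineSegment("IGKJ1", "IGK", "J", "TTTCAACAA"),
        GermlineSegment("IGKJ2", "IGK", "J", "TTTCCACCA"),
    ]
    return GermlineReference(segs)


@pytest.fixture(scope="session")
def fixture_reference() -> GermlineReference:
    return make_fixture_reference()


@pytest.fixture(scope="session")
def default_reference():
    from screpsim.germline import load_default_reference

    return load_default_reference()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def fast_settings(fixture_reference) -> RecombinationSettings:
    """Recombination without productivity filtering, on the tiny reference."""
    return RecombinationSettings(
        reference=fixture_reference, receptor="B", productive_only=False
    )


@pytest.fixture
def zero_div_settings(fixture_reference) -> RecombinationSettings:
    jm = JunctionModel.zero_diversification()
    return RecombinationSettings(
        reference=fixture_reference,
        receptor="B",
        productive_only=False,
        heavy_junction=jm,
        light_junction=jm,
    )
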