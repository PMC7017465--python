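"""Shared fixtures: tiny hand-built gene models and simulated pools."""

import warnings

import pytest

from canseq.reference import AmpliconReference, GeneModel


@pytest.fixture
def toy_gene() -> AmpliconReference:
    """Single-exon forward gene: ATG TGG GGC TAA (M W G stop)."""
    return AmpliconReference(
        "TOY", "ATGTGGGGCTAA", GeneModel([(0, 12)], "forward")
    )


@pytest.fixture
def toy_gene_reverse() -> AmpliconReference:
    """The toy gene on the reverse strand of its reverse complement."""
    return AmpliconReference(
        "YOT", "TTAGCCCCACAT", GeneModel([(0, 12)], "reverse")
    )


@pytest.fixture
def two_exon_gene() -> AmpliconReference:
    """Two-exon forward gene, CDS join(1..6,12..17), intron 7..11 (GTAAG)."""
    return AmpliconReference(
        "TWOEX", "ATGTGGGTAAGGGCTAA", GeneModel([(0, 6), (11, 17)], "forward")
    )


@pytest.fixture
def no_stop_warning():
    """Suppress partial-model warnings for deliberately odd fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
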