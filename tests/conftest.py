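import pytest

from pompevar import datasets
from pompevar.gene_model import DomainInterval, DomainMap, ExonSegment, GeneModel

# Toy CDS used throughout: ATG CCC GCT AAA TAG -> MPAK*
TOY_CDS = "ATGCCCGCTAAATAG"


@pytest.fixture
def toy_cds():
    return TOY_CDS


@pytest.fixture
def toy_model():
    """Three-exon model over the toy CDS: noncoding exon 1, then 1-6 / 7-15."""
    return GeneModel(
        gene_symbol="TOY",
        cds=TOY_CDS,
        exons=(
            ExonSegment(1, None, None),
            ExonSegment(2, 1, 6),
            ExonSegment(3, 7, 15),
        ),
    )


@pytest.fixture
def gaa_model():
    return datasets.gaa_like_gene_model()


@pytest.fixture
def gaa_domains():
    return datasets.gaa_domain_map()


@pytest.fixture
def cohort_rows():
    return datasets.iopd_cohort()


@pytest.fixture
def assay_records():
    return datasets.cos7_assay()


@pytest.fixture
def small_domain_map():
    return DomainMap(
        intervals=(
            DomainInterval("N-terminal beta-sheet", 261, 335),
            DomainInterval("catalytic GH31", 367, 689),
        )
    )
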