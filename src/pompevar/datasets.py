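"""Bundled reference inputs: the Thai IOPD cohort and COS-7 assay tables.

The cohort genotype table, the transfection-assay table, the prior Thai
allele counts, and the pseudodeficiency list are published clinical data
typed in verbatim.  The GAA gene model and domain map bundled here are
SYNTHETIC stand-ins: real exon/domain boundaries are not part of the
published record this package reproduces, so boundaries were chosen to be
consistent with every exon and domain assignment in the cohort table (in
particular exon 9 spans c.1327..1437, an in-frame 111 nt whose skip removes
37 residues) and the coding sequence itself is randomly generated.  Supply
your own gene-model/domain TSVs for work against the true reference.
"""

from __future__ import annotations

import io

import pandas as pd

from .cohort import ExternalCount, GenotypeRow, load_cohort
from .gene_model import DomainInterval, DomainMap, ExonSegment, GeneModel
from .severity import AssayRecord, WesternProfile
from .simulate import SimulationConfig, make_cds

IOPD_COHORT_TSV = """\
patient\tcdna\tprotein\texon\tzygosity\tparent\tdomain
P01\tc.876C>G\tp.Tyr292X\t5\thet\tFA\tN-terminal beta-sheet
P01\tc.1003G>A\tp.Gly335Arg\t6\thet\tMO\tN-terminal beta-sheet
P02\tc.1935C>A\tp.Asp645Glu\t14\thet\tFA\tcatalytic GH31
P02\tc.1933G>C\tp.Asp645His\t14\thet\tMO\tcatalytic GH31
P03\tc.1099T>C\tp.Trp367Arg\t7\thet\tFA\tcatalytic GH31
P03\tc.1942G>A\tp.Gly648Ser\t14\thet\tMO\tcatalytic GH31
P04\tc.1226insG\tp.Asp409GlyfsX95\t8\thet\tFA\tcatalytic GH31
P04\tc.2024_2026delACA\tp.Asn675del\t14\thet\tMO\tcatalytic GH31
P05\tc.1538A>G\tp.Asp513Gly\t10\thom\tboth\tcatalytic GH31
P06\tc.781G>A\tp.Ala261Thr\t4\thom\tboth\tN-terminal beta-sheet
P07\tc.1411_1414delGAGA\tp.Glu471fsX5\t9\thet\tMO\tcatalytic GH31
P07\tc.1933G>C\tp.Asp645His\t14\thet\tFA\tcatalytic GH31
P08\tc.877G>A\tp.Gly293Arg\t5\thom\tboth\tN-terminal beta-sheet
P09\tc.1941C>G\tp.Cys647Trp\t14\thom\tboth\tcatalytic GH31
P10\tc.876C>G\tp.Tyr292X\t5\thom\tboth\tN-terminal beta-sheet
P11\tc.1895T>G\tp.Leu632Arg\t14\thom\tboth\tcatalytic GH31
P12\tc.1327-2A>G\t-\tIVS8\thet\tMO\t-
P12\tc.1437G>C\tp.Lys479Asn\t9\thet\tFA\tcatalytic GH31
"""

COS7_ASSAY_TSV = """\
variant\tmedium_activity\tcell_activity\tM110\tC110\tC95\tC76
Wild type\t60.5\t631.3\t4,4\t4,4\t4,4\t4,4
p.Ala261Thr\t3.31\t478.3\t3,4\t4,4\t4,4\t4,4
p.Tyr292X\t0\t0\t1,1\t2,4\t2,4\t2,4
p.Asp513Gly\t0\t4.8\t1,1\t3,4\t2,4\t2,4
p.Leu632Arg\t0.05\t0.1\t1,1\t3,4\t2,4\t2,4
"""

# Published classes for the assay table above, for cross-checking.
COS7_EXPECTED_CLASSES = {
    "p.Ala261Thr": "D/E",
    "p.Tyr292X": "B",
    "p.Asp513Gly": "B",
    "p.Leu632Arg": "B",
}

# Prior Thai IOPD report: 10 mutant alleles, 8 of them p.Asp645Glu (exon 14);
# the remaining two alleles were not itemized.
PRIOR_THAI_COUNTS_TSV = """\
variant\texon\talleles
p.Asp645Glu\t14\t8
other\t-\t2
"""

PSEUDODEFICIENCY_ALLELES = ("p.Gly576Ser", "p.Glu689Lys", "c.1726G>A", "c.2065G>A")

ASP645_GROUP = ("p.Asp645Glu", "p.Asp645His")

# Synthetic exon boundaries consistent with every exon assignment above.
_GAA_EXON_TABLE = (
    (1, None, None),
    (2, 1, 680), (3, 681, 750), (4, 751, 860), (5, 861, 950),
    (6, 951, 1070), (7, 1071, 1195), (8, 1196, 1326), (9, 1327, 1437),
    (10, 1438, 1550), (11, 1551, 1650), (12, 1651, 1750), (13, 1751, 1880),
    (14, 1881, 2040), (15, 2041, 2150), (16, 2151, 2350), (17, 2351, 2550),
    (18, 2551, 2700), (19, 2701, 2800), (20, 2801, 2859),
)

# Synthetic domain boundaries consistent with every domain assignment above.
_GAA_DOMAIN_TABLE = (
    ("trefoil Type-P", 89, 135),
    ("N-terminal beta-sheet", 156, 336),
    ("catalytic GH31", 347, 726),
    ("proximal beta-sheet", 727, 820),
    ("distal beta-sheet", 821, 952),
)


def iopd_cohort() -> list[GenotypeRow]:
    """The 12-patient IOPD cohort genotype table (18 rows, 24 alleles)."""
    return load_cohort(io.StringIO(IOPD_COHORT_TSV))


def iopd_cohort_frame() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(IOPD_COHORT_TSV), sep="\t", dtype=str)


def cos7_assay() -> list[AssayRecord]:
    """The COS-7 transfection-assay table (wild type + four variants)."""
    frame = pd.read_csv(io.StringIO(COS7_ASSAY_TSV), sep="\t", dtype=str)
    records = []
    for rec in frame.itertuples(index=False):
        records.append(
            AssayRecord.from_values(
                rec.variant,
                float(rec.medium_activity),
                float(rec.cell_activity),
                WesternProfile.from_strings(rec.M110, rec.C110, rec.C95, rec.C76),
            )
        )
    return records


def prior_thai_counts() -> list[ExternalCount]:
    """Allele counts from the earlier Thai IOPD cohort (10 alleles)."""
    frame = pd.read_csv(io.StringIO(PRIOR_THAI_COUNTS_TSV), sep="\t", dtype=str)
    out = []
    for rec in frame.itertuples(index=False):
        exon = None if rec.exon in ("-", "", None) else int(rec.exon)
        out.append(ExternalCount(rec.variant, exon, int(rec.alleles)))
    return out


def gaa_like_gene_model() -> GeneModel:
    """A synthetic GAA-like gene model: 2859-bp random CDS, 20 exons.

    Exon boundaries match every exon assignment in the bundled cohort table;
    the sequence itself is synthetic (deterministic seed), so positional
    arithmetic and exon mapping are faithful while base identities are not.
    """
    cds = make_cds(SimulationConfig(seed=17, cds_length_codons=953))
    exons = tuple(ExonSegment(n, s, e) for n, s, e in _GAA_EXON_TABLE)
    return GeneModel(gene_symbol="GAA", cds=cds, exons=exons)


def gaa_domain_map() -> DomainMap:
    """Synthetic five-domain map consistent with the cohort's domain labels."""
    return DomainMap(
        intervals=tuple(DomainInterval(n, s, e) for n, s, e in _GAA_DOMAIN_TABLE)
    )
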