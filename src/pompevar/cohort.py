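"""Biallelic cohort genotype tables and allele-spectrum statistics.

A cohort table has one row per distinct allele of each patient (an autosomal
recessive design: every patient carries exactly two pathogenic alleles, so a
homozygous row contributes two).  Tallies count alleles per variant and per
exon, and distinct variants per protein domain; known pseudodeficiency
alleles (p.Gly576Ser, p.Glu689Lys in Asian populations) are excluded from
pathogenic tallies and reported separately.  External allele counts from
prior reports can be merged to refine hotspot fractions.
"""

from __future__ import annotations

import io as _io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import hgvs
from .errors import ValidationError
from .gene_model import DomainMap, GeneModel, domain_of_residue, exon_residue_span

INTRONIC = "intronic"
UNASSIGNED = "unassigned"
UNSPECIFIED_EXON = "unspecified"

COHORT_COLUMNS = ["patient", "cdna", "protein", "exon", "zygosity", "parent", "domain"]

PARENT_CODES = ("FA", "MO", "both", "unknown")


@dataclass(frozen=True)
class GenotypeRow:
    """One allele (or homozygous allele pair) of one patient."""

    patient_id: str
    cdna: str
    protein: Optional[str]
    exon: Optional[int]  # None = intronic variant without an exon number
    zygosity: str  # "het" | "hom"
    parent_of_origin: str = "unknown"
    domain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValidationError(f"zygosity must be het/hom, got {self.zygosity!r}")
        if self.parent_of_origin not in PARENT_CODES:
            raise ValidationError(f"parent must be one of {PARENT_CODES}, got {self.parent_of_origin!r}")

    @property
    def allele_count(self) -> int:
        return 2 if self.zygosity == "hom" else 1

    @property
    def variant_label(self) -> str:
        """Protein name when available, else the cDNA name (splice variants)."""
        if self.protein and self.protein not in ("-", "?"):
            return self.protein
        return self.cdna


def _parse_exon_field(value: object) -> Optional[int]:
    if value is None:
        return None
    text = str(value).strip()
    if text in ("", "-", "NA", "nan") or text.upper().startswith("IVS") or text == INTRONIC:
        return None
    try:
        return int(float(text))
    except ValueError:
        raise ValidationError(f"cannot parse exon field {text!r}") from None


def rows_from_frame(frame: pd.DataFrame) -> list[GenotypeRow]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    rows = []
    for rec in frame.itertuples(index=False):
        domain = getattr(rec, "domain")
        domain = None if domain is None or str(domain).strip() in ("", "-", "nan") else str(domain).strip()
        protein = getattr(rec, "protein")
        protein = None if protein is None or str(protein).strip() in ("", "nan") else str(protein).strip()
        rows.append(
            GenotypeRow(
                patient_id=str(rec.patient).strip(),
                cdna=str(rec.cdna).strip(),
                protein=protein,
                exon=_parse_exon_field(rec.exon),
                zygosity=str(rec.zygosity).strip().lower(),
                parent_of_origin=str(rec.parent).strip(),
                domain=domain,
            )
        )
    return rows


def validate_biallelic(rows: Sequence[GenotypeRow]) -> None:
    """Every patient must carry exactly two alleles."""
    per_patient: Counter[str] = Counter()
    for row in rows:
        per_patient[row.patient_id] += row.allele_count
    bad = {p: n for p, n in per_patient.items() if n != 2}
    if bad:
        worst = ", ".join(f"{p} has {n}" for p, n in sorted(bad.items()))
        raise ValidationError(f"patients without exactly 2 alleles: {worst}")


def load_cohort(source: Union[str, _io.IOBase]) -> list[GenotypeRow]:
    """Read and validate a tab-separated cohort table; empty file -> empty cohort."""
    try:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    rows = rows_from_frame(frame)
    validate_biallelic(rows)
    return rows


@dataclass(frozen=True)
class ExternalCount:
    """Allele count of one variant from a previously published cohort."""

    variant_label: str
    exon: Optional[int]
    alleles: int

    def __post_init__(self) -> None:
        if self.alleles < 1:
            raise ValidationError("external allele count must be >= 1")


@dataclass
class AlleleTally:
    """Allele counts per variant and exon, plus distinct variants per domain."""

    variant_counts: Counter = field(default_factory=Counter)
    exon_counts: Counter = field(default_factory=Counter)  # keys: int | "intronic" | "unspecified"
    domain_variants: dict = field(default_factory=lambda: defaultdict(set))
    total_alleles: int = 0
    n_patients: int = 0
    excluded_pseudodeficiency: list = field(default_factory=list)

    @property
    def distinct_variants(self) -> int:
        return len(self.variant_counts)


def tally(
    rows: Sequence[GenotypeRow],
    pseudodeficiency: Iterable[str] = (),
) -> AlleleTally:
    """Count alleles, excluding pseudodeficiency variants from pathogenic totals.

    Pseudodeficiency membership is matched against both protein and cDNA
    names; excluded rows are listed as ``(variant_label, alleles)``.
    """
    pseudo = set(pseudodeficiency)
    out = AlleleTally()
    patients = set()
    for row in rows:
        patients.add(row.patient_id)
        if row.variant_label in pseudo or row.cdna in pseudo or (row.protein or "") in pseudo:
            out.excluded_pseudodeficiency.append((row.variant_label, row.allele_count))
            continue
        n = row.allele_count
        out.variant_counts[row.variant_label] += n
        out.exon_counts[row.exon if row.exon is not None else INTRONIC] += n
        out.domain_variants[row.domain or UNASSIGNED].add(row.variant_label)
        out.total_alleles += n
    out.n_patients = len(patients)
    return out


def merge_external(base: AlleleTally, external: Iterable[ExternalCount]) -> AlleleTally:
    """Add published allele counts to a tally (denominators grow accordingly)."""
    merged = AlleleTally(
        variant_counts=Counter(base.variant_counts),
        exon_counts=Counter(base.exon_counts),
        domain_variants=defaultdict(set, {k: set(v) for k, v in base.domain_variants.items()}),
        total_alleles=base.total_alleles,
        n_patients=base.n_patients,
        excluded_pseudodeficiency=list(base.excluded_pseudodeficiency),
    )
    for item in external:
        merged.variant_counts[item.variant_label] += item.alleles
        merged.exon_counts[item.exon if item.exon is not None else UNSPECIFIED_EXON] += item.alleles
        merged.total_alleles += item.alleles
    return merged


def percent(count: int, total: int) -> float:
    """Percentage, half-up to one decimal (11/34 -> 32.4)."""
    if total == 0:
        raise ValidationError("cannot take a fraction of an empty tally")
    d = Decimal(count) * 100 / Decimal(total)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def exon_fraction(t: AlleleTally, exons: Union[int, Sequence[int]]) -> tuple[int, int, float]:
    """Allele count, total, and percent for one exon or a set of exons."""
    wanted = {exons} if isinstance(exons, int) else set(exons)
    count = sum(n for exon, n in t.exon_counts.items() if exon in wanted)
    return count, t.total_alleles, percent(count, t.total_alleles)


def variant_group_fraction(
    t: AlleleTally, labels: Iterable[str]
) -> tuple[int, int, float]:
    """Combined allele fraction of a group of variant labels (e.g. p.Asp645Glu/His)."""
    wanted = set(labels)
    count = sum(n for label, n in t.variant_counts.items() if label in wanted)
    return count, t.total_alleles, percent(count, t.total_alleles)


def splice_loss_domains(
    rows: Sequence[GenotypeRow], model: GeneModel, domains: DomainMap
) -> dict[str, set[str]]:
    """Domains lost by canonical-splice variants in the cohort.

    A variant at an intron/exon boundary (offset ±1/±2) is assumed to skip
    the adjacent exon; the domains overlapped by the skipped exon's residue
    span are reported, keyed by the variant's label.
    """
    out: dict[str, set[str]] = {}
    for row in rows:
        try:
            variant = hgvs.parse_cdna(row.cdna)
        except Exception:
            continue
        if variant.intron_offset is None or abs(variant.intron_offset) > 2:
            continue
        # acceptor-side offsets (<0) precede the exon starting at the anchor
        # position; donor-side offsets (>0) follow the exon ending there.
        exon_number = None
        for exon in model.coding_exons:
            if variant.intron_offset < 0 and exon.cds_start == variant.start:
                exon_number = exon.number
            if variant.intron_offset > 0 and exon.cds_end == variant.start:
                exon_number = exon.number
        if exon_number is None:
            continue
        first, last = exon_residue_span(model, exon_number)
        hit = {
            domain_of_residue(domains, r)
            for r in range(first, last + 1)
        }
        hit.discard("interdomain")
        out[row.variant_label] = hit
    return out


@dataclass(frozen=True)
class DomainSpectrum:
    """Distinct-variant counts per domain with a catalytic-or-loss aggregate."""

    per_domain: dict
    catalytic_or_loss: int
    total_distinct: int
    unassigned: tuple[str, ...]


def domain_spectrum(
    rows: Sequence[GenotypeRow],
    catalytic_loss: Iterable[str] = (),
    catalytic_domain: str = "catalytic GH31",
) -> DomainSpectrum:
    """Distinct variants per domain; unmapped variants are listed, not dropped.

    ``catalytic_loss`` names variants (e.g. a splice allele skipping an exon
    inside the catalytic domain, or a frameshift truncating upstream of it)
    counted in the catalytic-or-loss aggregate although they carry no domain
    label of their own.
    """
    by_domain: dict[str, set[str]] = defaultdict(set)
    all_labels: set[str] = set()
    for row in rows:
        by_domain[row.domain or UNASSIGNED].add(row.variant_label)
        all_labels.add(row.variant_label)
    loss = set(catalytic_loss) & all_labels
    catalytic = set(by_domain.get(catalytic_domain, set()))
    return DomainSpectrum(
        per_domain={k: len(v) for k, v in sorted(by_domain.items())},
        catalytic_or_loss=len(catalytic | loss),
        total_distinct=len(all_labels),
        unassigned=tuple(sorted(by_domain.get(UNASSIGNED, set()))),
    )
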