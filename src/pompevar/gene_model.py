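"""Reference coding sequence, exon structure, and protein-domain intervals.

Coordinates follow the HGVS ``c.`` convention: 1-based, with position 1 the A
of the ATG start codon.  Exon intervals are CDS coordinates (noncoding exons,
such as GAA exon 1, carry no interval).  Protein coordinates are 1-based
residue numbers; the terminal stop codon is not a residue, so a CDS of
``3*(n+1)`` bases encodes ``n`` residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import CoordinateError, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

INTERDOMAIN = "interdomain"


@dataclass(frozen=True)
class ExonSegment:
    """One exon of a gene model; ``cds_start``/``cds_end`` are None for noncoding exons."""

    number: int
    cds_start: Optional[int]
    cds_end: Optional[int]

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def cds_length(self) -> int:
        if not self.coding:
            return 0
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence plus its exon decomposition."""

    gene_symbol: str
    cds: str
    exons: tuple[ExonSegment, ...]

    @property
    def protein_length(self) -> int:
        """Number of encoded residues, excluding the terminal stop."""
        return len(self.cds) // 3 - 1

    @property
    def coding_exons(self) -> tuple[ExonSegment, ...]:
        return tuple(e for e in self.exons if e.coding)


@dataclass(frozen=True)
class DomainInterval:
    domain_name: str
    start_residue: int
    end_residue: int


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping protein-domain intervals (1-based, inclusive)."""

    intervals: tuple[DomainInterval, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in self.intervals:
            if iv.end_residue < iv.start_residue:
                raise ValidationError(
                    f"domain {iv.domain_name!r}: end {iv.end_residue} < start {iv.start_residue}"
                )
            if iv.start_residue <= prev_end:
                raise ValidationError(
                    f"domain {iv.domain_name!r} overlaps or is out of order at residue {iv.start_residue}"
                )
            prev_end = iv.end_residue

    def validate_against(self, protein_length: int) -> list[str]:
        return [
            f"domain {iv.domain_name!r} extends past protein length {protein_length}"
            for iv in self.intervals
            if iv.end_residue > protein_length
        ]


def codon_of_position(cds_position: int, cds_length: int) -> tuple[int, int]:
    """Map a 1-based CDS position to ``(codon_index, offset_in_codon)``.

    Offset is 1, 2 or 3 within the codon, so c.876 (third base of codon 292)
    maps to ``(292, 3)``.
    """
    if cds_position < 1:
        raise CoordinateError(f"cDNA position {cds_position} < 1")
    if cds_position > cds_length:
        raise CoordinateError(f"cDNA position {cds_position} > CDS length {cds_length}")
    return math.ceil(cds_position / 3), (cds_position - 1) % 3 + 1


def position_of_codon(codon_index: int, offset: int, cds_length: int) -> int:
    """Inverse of :func:`codon_of_position`."""
    if offset not in (1, 2, 3):
        raise CoordinateError(f"codon offset {offset} not in 1..3")
    pos = (codon_index - 1) * 3 + offset
    if not 1 <= pos <= cds_length:
        raise CoordinateError(f"codon {codon_index} offset {offset} outside CDS of length {cds_length}")
    return pos


def exon_of_position(model: GeneModel, cds_position: int) -> int:
    """Exon number whose CDS interval contains the position (inclusive bounds)."""
    if cds_position < 1:
        raise CoordinateError(f"cDNA position {cds_position} < 1")
    for exon in model.exons:
        if exon.coding and exon.cds_start <= cds_position <= exon.cds_end:
            return exon.number
    raise CoordinateError(
        f"cDNA position {cds_position} outside all exon intervals of {model.gene_symbol}"
    )


def domain_of_residue(domain_map: DomainMap, residue: int) -> str:
    """Domain name containing the residue, or ``"interdomain"``."""
    if residue < 1:
        raise CoordinateError(f"residue {residue} < 1")
    for iv in domain_map.intervals:
        if iv.start_residue <= residue <= iv.end_residue:
            return iv.domain_name
    return INTERDOMAIN


def exon_residue_span(model: GeneModel, exon_number: int) -> tuple[int, int]:
    """First and last residue whose codon overlaps the exon's CDS interval."""
    exon = _find_exon(model, exon_number)
    first, _ = codon_of_position(exon.cds_start, len(model.cds))
    last, _ = codon_of_position(exon.cds_end, len(model.cds))
    return first, min(last, model.protein_length)


def exon_skip_consequence(model: GeneModel, exon_number: int) -> tuple[bool, Optional[int]]:
    """Reading-frame effect of skipping one exon.

    Returns ``(in_frame, residues_lost)``; an exon whose CDS length is a
    multiple of 3 deletes ``length/3`` residues in frame (e.g. a 111-nt exon
    removes 37 residues), anything else shifts the frame.
    """
    exon = _find_exon(model, exon_number)
    length = exon.cds_length
    if length % 3 == 0:
        return True, length // 3
    return False, None


def _find_exon(model: GeneModel, exon_number: int) -> ExonSegment:
    for exon in model.exons:
        if exon.number == exon_number:
            if not exon.coding:
                raise ValidationError(f"exon {exon_number} has no CDS")
            return exon
    raise CoordinateError(f"no exon {exon_number} in model for {model.gene_symbol}")


def validate_gene_model(model: GeneModel) -> list[str]:
    """Check every structural invariant; returns human-readable violations.

    An empty list means the model is sound: exon intervals sorted,
    non-overlapping, and jointly covering 1..len(cds); CDS length a multiple
    of 3; terminal stop codon present; no in-frame internal stop; bases ACGT.
    """
    violations: list[str] = []
    cds = model.cds.upper()
    bad = set(cds) - set("ACGT")
    if bad:
        violations.append(f"non-ACGT characters in CDS: {sorted(bad)}")
        return violations

    if len(cds) % 3 != 0:
        violations.append(f"CDS length {len(cds)} not a multiple of 3")
    else:
        if len(cds) < 6:
            violations.append("CDS shorter than start + stop codon")
        else:
            if cds[-3:] not in STOP_CODONS:
                violations.append("missing terminal stop codon")
            internal = [
                i + 1
                for i in range(0, len(cds) - 3, 3)
                if cds[i : i + 3] in STOP_CODONS
            ]
            if internal:
                violations.append(f"internal in-frame stop codon at c.{internal[0]}")

    coding = [e for e in model.exons if e.coding]
    covered = 0
    prev_end = 0
    for exon in coding:
        if exon.cds_end < exon.cds_start:
            violations.append(f"exon {exon.number}: cds_end < cds_start")
            continue
        if exon.cds_start != prev_end + 1:
            violations.append(
                f"exon {exon.number}: interval starts at {exon.cds_start}, expected {prev_end + 1}"
            )
        prev_end = exon.cds_end
        covered += exon.cds_length
    if coding:
        if covered != len(cds):
            violations.append(
                f"exon CDS intervals cover {covered} bases, CDS has {len(cds)}"
            )
        if prev_end != len(cds):
            violations.append(f"last exon ends at {prev_end}, CDS has {len(cds)} bases")
    return violations
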