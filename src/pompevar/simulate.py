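"""Synthetic fixtures: coding sequences, gene models, cohorts, assay tables.

Every generator is driven by a single integer seed and emulates the shape of
the real study inputs: a ~2.9 kb CDS split over ~20 exons, a 12-patient
biallelic cohort with a concentrated allele spectrum and homozygotes, and a
transfection-assay table whose true activities are class-consistent with
multiplicative lognormal noise (enzyme assays are positive and CV-scaled;
the wild-type replicate scatter in such assays is around 7% CV, the default
here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import hgvs
from .errors import ValidationError
from .gene_model import (
    DomainInterval,
    DomainMap,
    ExonSegment,
    GeneModel,
    STOP_CODONS,
    codon_of_position,
    domain_of_residue,
    exon_of_position,
)
from .severity import BandCode, WesternProfile

_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)

# (true M%, true C%, band codes M110/C110/C95/C76) per severity class.
DEFAULT_CLASS_TEMPLATES: dict[str, tuple[float, float, tuple[str, str, str, str]]] = {
    "A": (0.5, 0.5, ("1,1", "1,1", "1,1", "1,1")),
    "B": (0.5, 2.5, ("1,1", "3,4", "2,4", "2,4")),
    "C": (4.0, 6.0, ("2,4", "3,4", "3,4", "3,4")),
    "D": (15.0, 15.0, ("3,4", "3,4", "3,4", "3,4")),
    "E": (45.0, 45.0, ("3,4", "4,4", "4,4", "4,4")),
    "F": (95.0, 95.0, ("4,4", "4,4", "4,4", "4,4")),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all generators; the seed fixes every draw."""

    seed: int = 0
    cds_length_codons: int = 953
    n_exons: int = 20
    n_patients: int = 12
    allele_spectrum: Optional[tuple[tuple[str, float], ...]] = None  # (c. string, freq)
    hom_fraction: float = 0.3
    noise_cv: float = 0.07
    class_templates: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_TEMPLATES))

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not 0 <= self.hom_fraction <= 1:
            raise ValidationError("hom_fraction must be a probability")
        if self.allele_spectrum is not None:
            total = sum(f for _, f in self.allele_spectrum)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"allele frequencies sum to {total}, expected 1")


def make_cds(config: SimulationConfig) -> str:
    """A random valid CDS: ATG, no internal in-frame stop, one terminal stop."""
    n = config.cds_length_codons
    if n < 2:
        raise ValidationError("cds_length_codons must be >= 2")
    rng = np.random.default_rng(config.seed)
    middle = rng.choice(len(_SENSE_CODONS), size=n - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + str(stop)


def make_gene_model(config: SimulationConfig, gene_symbol: str = "SYN1") -> GeneModel:
    """A random gene model over :func:`make_cds`: noncoding exon 1 plus coding exons."""
    cds = make_cds(config)
    rng = np.random.default_rng(config.seed + 1)
    n_coding = max(1, config.n_exons - 1)
    if len(cds) < n_coding:
        raise ValidationError("CDS too short for requested exon count")
    cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_coding - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(cds)]
    exons = [ExonSegment(1, None, None)]
    for i in range(n_coding):
        exons.append(ExonSegment(i + 2, bounds[i] + 1, bounds[i + 1]))
    return GeneModel(gene_symbol=gene_symbol, cds=cds, exons=tuple(exons))


def make_domain_map(model: GeneModel, n_domains: int = 3, seed: int = 0) -> DomainMap:
    """Random non-overlapping domain intervals over a model's protein."""
    rng = np.random.default_rng(seed + 2)
    length = model.protein_length
    cuts = np.sort(rng.choice(np.arange(2, length), size=2 * n_domains, replace=False))
    intervals = tuple(
        DomainInterval(f"domain{i + 1}", int(cuts[2 * i]), int(cuts[2 * i + 1]) - 1)
        for i in range(n_domains)
    )
    return DomainMap(intervals=intervals)


def _annotate(cdna: str, model: GeneModel, domains: Optional[DomainMap]) -> tuple[str, object, object]:
    """(protein label, exon field, domain field) for a spectrum variant."""
    variant = hgvs.parse_cdna(cdna)
    if variant.intron_offset is not None:
        return "-", "intronic", "-"
    consequence = hgvs.derive_consequence(model.cds, variant)
    protein = hgvs.format_hgvs_p(consequence)
    exon = exon_of_position(model, variant.start)
    domain = "-"
    if domains is not None and consequence.residue is not None:
        domain = domain_of_residue(domains, consequence.residue)
    return protein, exon, domain


def make_cohort(
    config: SimulationConfig,
    model: Optional[GeneModel] = None,
    domains: Optional[DomainMap] = None,
) -> pd.DataFrame:
    """A biallelic cohort table drawn from the configured allele spectrum.

    Each patient receives either one homozygous allele (probability
    ``hom_fraction``) or two independent draws from the spectrum; realized
    frequencies therefore sit within binomial error of the targets.
    """
    if model is None:
        model = make_gene_model(config)
    spectrum = config.allele_spectrum
    if spectrum is None:
        spectrum = _default_spectrum(model, config.seed)
    labels = [c for c, _ in spectrum]
    freqs = np.array([f for _, f in spectrum])
    annotations = {c: _annotate(c, model, domains) for c in labels}

    rng = np.random.default_rng(config.seed + 3)
    records = []
    for p in range(config.n_patients):
        pid = f"S{p + 1:03d}"
        if rng.random() < config.hom_fraction:
            picks = [labels[rng.choice(len(labels), p=freqs)]] * 2
        else:
            picks = [labels[rng.choice(len(labels), p=freqs)] for _ in range(2)]
        if picks[0] == picks[1]:
            alleles = [(picks[0], "hom", "both")]
        else:
            alleles = [(picks[0], "het", "FA"), (picks[1], "het", "MO")]
        for cdna, zyg, parent in alleles:
            protein, exon, domain = annotations[cdna]
            records.append((pid, cdna, protein, exon, zyg, parent, domain))
    return pd.DataFrame(
        records,
        columns=["patient", "cdna", "protein", "exon", "zygosity", "parent", "domain"],
    )


def _default_spectrum(model: GeneModel, seed: int) -> tuple[tuple[str, float], ...]:
    """A hotspot-like spectrum: one major substitution plus minor alleles."""
    rng = np.random.default_rng(seed + 4)
    cds = model.cds
    positions = rng.choice(np.arange(4, len(cds) - 3), size=4, replace=False)
    variants = []
    for pos in positions.tolist():
        ref = cds[pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        variants.append(f"c.{pos}{ref}>{alt}")
    return (
        (variants[0], 0.375),
        (variants[1], 0.25),
        (variants[2], 0.25),
        (variants[3], 0.125),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma))


def make_assay_dataset(
    config: SimulationConfig,
    classes: Sequence[str] = ("A", "B", "C", "D", "E", "F"),
    n_per_class: int = 1,
    wildtype_medium: float = 60.0,
    wildtype_cell: float = 600.0,
) -> pd.DataFrame:
    """A transfection-assay table with class-consistent noisy activities.

    The wild-type row is noiseless, so normalizing a noiseless mutant
    recovers the template M%/C% exactly; mutant activities carry lognormal
    noise at ``noise_cv``.
    """
    missing = [c for c in classes if c not in config.class_templates]
    if missing:
        raise ValidationError(f"no class template for {missing}")
    rng = np.random.default_rng(config.seed + 5)
    rows = [("Wild type", wildtype_medium, wildtype_cell, "4,4", "4,4", "4,4", "4,4")]
    for cls in classes:
        m_pct, c_pct, bands = config.class_templates[cls]
        for i in range(n_per_class):
            medium = wildtype_medium * m_pct / 100 * _lognormal_factor(rng, config.noise_cv)
            cell = wildtype_cell * c_pct / 100 * _lognormal_factor(rng, config.noise_cv)
            label = f"{cls}" if n_per_class == 1 else f"{cls}_{i + 1}"
            rows.append((label, round(medium, 4), round(cell, 4), *bands))
    return pd.DataFrame(
        rows,
        columns=["variant", "medium_activity", "cell_activity", "M110", "C110", "C95", "C76"],
    )


def template_profile(bands: tuple[str, str, str, str]) -> WesternProfile:
    return WesternProfile(*(BandCode.from_string(b) for b in bands))


def random_variant(
    rng: np.random.Generator,
    cds: str,
    kinds: Sequence[str] = ("substitution", "deletion", "insertion", "duplication", "delins"),
) -> hgvs.CodingVariant:
    """A random applicable exonic variant on a CDS (ref bases filled in)."""
    kind = kinds[rng.choice(len(kinds))]
    last = len(cds)
    if kind == "substitution":
        pos = int(rng.integers(1, last + 1))
        ref = cds[pos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        return hgvs.CodingVariant(kind="substitution", start=pos, end=pos,
                                  ref_bases=ref, alt_bases=alt)
    if kind == "insertion":
        pos = int(rng.integers(1, last))
        seq = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 7))))
        return hgvs.CodingVariant(kind="insertion", start=pos, end=pos + 1, alt_bases=seq)
    span = int(rng.integers(1, 7))
    start = int(rng.integers(1, max(2, last - span)))
    end = start + span - 1
    segment = cds[start - 1 : end]
    if kind == "deletion":
        return hgvs.CodingVariant(kind="deletion", start=start, end=end, ref_bases=segment)
    if kind == "duplication":
        return hgvs.CodingVariant(kind="duplication", start=start, end=end, ref_bases=segment)
    seq = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 7))))
    return hgvs.CodingVariant(kind="delins", start=start, end=end, alt_bases=seq)
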