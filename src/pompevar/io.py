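"""Readers and writers for the package's tab-separated and FASTA dialects.

All tables are UTF-8 TSV with a header row; band codes are serialized as
printed in assay reports ("2,4").  JSON reports carry a schema version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import ExternalCount
from .errors import ValidationError
from .gene_model import DomainInterval, DomainMap, ExonSegment, GeneModel
from .restriction import EnzymeDef
from .severity import AssayRecord, RatedVariant, WesternProfile

REPORT_SCHEMA = "pompevar-report/1"

PathLike = Union[str, Path]


def read_cds_fasta(path: PathLike) -> tuple[str, str]:
    """(record id, sequence) of the single record in a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_cds_fasta(path: PathLike, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_gene_model_tsv(path: PathLike, cds: str, gene_symbol: str = "gene") -> GeneModel:
    """Gene model from a TSV with columns exon/cds_start/cds_end.

    Empty start/end fields mark noncoding exons.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"exon", "cds_start", "cds_end"}
    if not needed.issubset(frame.columns):
        raise ValidationError(f"gene model table needs columns {sorted(needed)}")
    exons = []
    for rec in frame.itertuples(index=False):
        start = rec.cds_start
        end = rec.cds_end
        empty = lambda v: v is None or str(v).strip() in ("", "-", "nan")
        exons.append(
            ExonSegment(
                int(rec.exon),
                None if empty(start) else int(float(start)),
                None if empty(end) else int(float(end)),
            )
        )
    return GeneModel(gene_symbol=gene_symbol, cds=cds.upper(), exons=tuple(exons))


def read_domain_map_tsv(path: PathLike) -> DomainMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"domain", "start_res", "end_res"}
    if not needed.issubset(frame.columns):
        raise ValidationError(f"domain map table needs columns {sorted(needed)}")
    return DomainMap(
        intervals=tuple(
            DomainInterval(str(r.domain), int(r.start_res), int(r.end_res))
            for r in frame.itertuples(index=False)
        )
    )


def read_enzymes_tsv(path: PathLike) -> tuple[EnzymeDef, ...]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"name", "iupac_site"}
    if not needed.issubset(frame.columns):
        raise ValidationError(f"enzyme table needs columns {sorted(needed)}")
    return tuple(EnzymeDef(str(r.name), str(r.iupac_site)) for r in frame.itertuples(index=False))


def read_assay_tsv(path: PathLike) -> list[AssayRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"variant", "medium_activity", "cell_activity", "M110", "C110", "C95", "C76"}
    if not needed.issubset(frame.columns):
        raise ValidationError(f"assay table needs columns {sorted(needed)}")
    return [
        AssayRecord.from_values(
            str(r.variant),
            float(r.medium_activity),
            float(r.cell_activity),
            WesternProfile.from_strings(r.M110, r.C110, r.C95, r.C76),
        )
        for r in frame.itertuples(index=False)
    ]


def read_external_counts_tsv(path: PathLike) -> list[ExternalCount]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"variant", "exon", "alleles"}
    if not needed.issubset(frame.columns):
        raise ValidationError(f"external counts table needs columns {sorted(needed)}")
    out = []
    for r in frame.itertuples(index=False):
        exon = None if r.exon is None or str(r.exon).strip() in ("", "-", "nan") else int(r.exon)
        out.append(ExternalCount(str(r.variant), exon, int(r.alleles)))
    return out


def read_variant_list(path: PathLike) -> list[str]:
    """One HGVS c. string per line; blank lines and # comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.strip().startswith("#")]


def rated_to_frame(rated: Sequence[RatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant_label,
                "m_pct_wt": r.normalized.m_report,
                "c_pct_wt": r.normalized.c_report,
                "class": r.class_string,
            }
            for r in rated
        ]
    )


def write_report_json(path: PathLike, payload: dict) -> None:
    body = {"schema": REPORT_SCHEMA, **payload}
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")
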