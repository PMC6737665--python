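"""HGVS cDNA variant parsing, application, and protein-consequence naming.

Supports the descriptions used in clinical GAA reports: substitutions
(``c.876C>G``), intronic substitutions with offsets (``c.1327-2A>G``,
``c.858+24G>C``), range deletions (``c.1411_1414delGAGA``), insertions in
both the strict between-bases dialect (``c.10_11insA``) and the legacy
single-position dialect (``c.1226insG``, meaning insertion after the stated
base), duplications, and deletion-insertions.

Protein consequences are derived by editing the coding sequence and
comparing translations, after shifting ambiguous insertions/deletions to
their most 3' position as HGVS requires.  Two ``p.`` dialects are emitted:
the modern one (``p.Tyr292Ter``, ``fsTer95``) and the legacy clinical one
(``p.Tyr292X``, ``fsX95``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .errors import (
    HgvsParseError,
    ReferenceMismatchError,
    UnsupportedVariantError,
    ValidationError,
)

KINDS = ("substitution", "deletion", "insertion", "duplication", "delins")

CATEGORIES = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_deletion",
    "inframe_insertion",
    "start_loss",
    "stop_loss",
    "splice_canonical",
    "intronic",
    "no_stop_found_frameshift",
)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


@dataclass(frozen=True)
class CodingVariant:
    """A parsed HGVS ``c.`` description.

    ``start``/``end`` are 1-based CDS positions; for insertions they bracket
    the insertion point (``end == start + 1``).  ``intron_offset`` carries the
    signed offset of intronic substitutions (−2 in ``c.1327-2A>G``).
    """

    kind: str
    start: int
    end: int
    intron_offset: Optional[int] = None
    ref_bases: Optional[str] = None
    alt_bases: Optional[str] = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.start > self.end:
            raise ValidationError(f"variant start {self.start} > end {self.end}")
        if self.kind == "substitution" and (
            not self.ref_bases or not self.alt_bases
            or len(self.ref_bases) != 1 or len(self.alt_bases) != 1
        ):
            raise ValidationError("substitution requires exactly one ref and one alt base")
        if self.kind == "insertion" and self.end != self.start + 1:
            raise ValidationError("insertion must sit between adjacent bases")
        if self.intron_offset == 0:
            raise ValidationError("intron offset of 0 is meaningless")

    @property
    def length_delta(self) -> int:
        """Length change the variant causes when applied to a sequence."""
        span = self.end - self.start + 1
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -span
        if self.kind == "insertion":
            return len(self.alt_bases)
        if self.kind == "duplication":
            return span
        return len(self.alt_bases or "") - span  # delins


_SUB = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$", re.IGNORECASE)
_DELINS = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$", re.IGNORECASE)
_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$", re.IGNORECASE)
_DUP = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGT]*)$", re.IGNORECASE)
_INS = re.compile(r"^c\.(\d+)(?:_(\d+))?ins([ACGT]+)$", re.IGNORECASE)


def _expand_truncated_end(start: int, start_txt: str, end_txt: str) -> int:
    """Resolve shorthand range ends like ``c.1411_14del`` -> 1414.

    Clinical reports sometimes truncate the end coordinate to its changing
    trailing digits; when the printed end is shorter than the start and would
    precede it, the missing leading digits are borrowed from the start.
    """
    end = int(end_txt)
    if end >= start:
        return end
    if len(end_txt) < len(start_txt):
        candidate = int(start_txt[: len(start_txt) - len(end_txt)] + end_txt)
        if candidate >= start:
            return candidate
    raise HgvsParseError(f"range end {end_txt!r} precedes start {start_txt!r}")


def parse_cdna(text: str) -> CodingVariant:
    """Parse an HGVS ``c.`` string into a :class:`CodingVariant`."""
    text = text.strip()
    if not text.startswith("c."):
        raise HgvsParseError(f"variant must start with 'c.': {text!r}")

    m = _SUB.match(text)
    if m:
        pos_txt, off_txt, ref, alt = m.groups()
        offset = int(off_txt) if off_txt else None
        return CodingVariant(
            kind="substitution", start=int(pos_txt), end=int(pos_txt),
            intron_offset=offset, ref_bases=ref.upper(), alt_bases=alt.upper(),
            raw=text,
        )

    for pattern, kind in ((_DELINS, "delins"), (_DEL, "deletion"), (_DUP, "duplication")):
        m = pattern.match(text)
        if m:
            start_txt, end_txt, bases = m.groups()
            start = int(start_txt)
            end = _expand_truncated_end(start, start_txt, end_txt) if end_txt else start
            ref = bases.upper() if bases and kind in ("deletion", "duplication") else None
            if ref is not None and len(ref) != end - start + 1:
                raise HgvsParseError(
                    f"{kind} states {len(ref)} bases for a {end - start + 1}-base range: {text!r}"
                )
            return CodingVariant(
                kind=kind, start=start, end=end, ref_bases=ref,
                alt_bases=bases.upper() if kind == "delins" else None, raw=text,
            )

    m = _INS.match(text)
    if m:
        start_txt, end_txt, bases = m.groups()
        start = int(start_txt)
        if end_txt is None:
            # Legacy single-position dialect: insertion AFTER the stated base.
            end = start + 1
        else:
            end = int(end_txt)
            if end != start + 1:
                raise HgvsParseError(
                    f"insertion must be between adjacent bases, got {start}_{end}: {text!r}"
                )
        return CodingVariant(
            kind="insertion", start=start, end=end, alt_bases=bases.upper(), raw=text
        )

    if re.search(r"(inv|con|ext|\[|\])", text):
        raise UnsupportedVariantError(f"unsupported variant kind in {text!r}")
    token = re.sub(r"^c\.[\d_+-]*", "", text) or text
    raise HgvsParseError(f"cannot parse {text!r} (offending token: {token!r})")


def format_cdna(variant: CodingVariant) -> str:
    """Canonical HGVS ``c.`` string for a variant (strict dialect)."""
    v = variant
    if v.kind == "substitution":
        off = "" if v.intron_offset is None else f"{v.intron_offset:+d}"
        return f"c.{v.start}{off}{v.ref_bases}>{v.alt_bases}"
    span = f"{v.start}" if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "deletion":
        return f"c.{span}del{v.ref_bases or ''}"
    if v.kind == "duplication":
        return f"c.{span}dup{v.ref_bases or ''}"
    if v.kind == "delins":
        return f"c.{span}delins{v.alt_bases}"
    return f"c.{v.start}_{v.end}ins{v.alt_bases}"


def _check_bounds(cds: str, variant: CodingVariant) -> None:
    last = len(cds)
    if variant.kind == "insertion":
        if not 1 <= variant.start < last:
            raise ReferenceMismatchError(
                f"insertion point {variant.start} outside CDS of length {last}"
            )
        return
    if not (1 <= variant.start and variant.end <= last):
        raise ReferenceMismatchError(
            f"variant span c.{variant.start}_{variant.end} outside CDS of length {last}"
        )


def apply_variant(cds: str, variant: CodingVariant) -> str:
    """Return the coding sequence edited by an exonic variant.

    Stated reference bases are verified against the sequence first; an
    intronic variant cannot be applied to a CDS and raises.
    """
    if variant.intron_offset is not None:
        raise ValidationError("cannot apply intronic variant to CDS")
    cds = cds.upper()
    _check_bounds(cds, variant)
    s, e = variant.start, variant.end

    if variant.kind == "substitution":
        found = cds[s - 1]
        if found != variant.ref_bases:
            raise ReferenceMismatchError(
                f"reference mismatch at c.{s}: expected {variant.ref_bases} found {found}"
            )
        return cds[: s - 1] + variant.alt_bases + cds[s:]

    if variant.kind in ("deletion", "duplication", "delins"):
        segment = cds[s - 1 : e]
        if variant.ref_bases is not None and segment != variant.ref_bases:
            raise ReferenceMismatchError(
                f"reference mismatch at c.{s}: expected {variant.ref_bases} found {segment}"
            )
        if variant.kind == "deletion":
            return cds[: s - 1] + cds[e:]
        if variant.kind == "duplication":
            return cds[:e] + segment + cds[e:]
        return cds[: s - 1] + variant.alt_bases + cds[e:]

    # insertion between s and s+1
    return cds[:s] + variant.alt_bases + cds[s:]


def normalize_3prime(cds: str, variant: CodingVariant) -> CodingVariant:
    """Shift an ambiguous deletion/insertion/duplication to its most 3' position.

    The edited sequence is unchanged by normalization; only the description
    moves, as the HGVS 3' rule requires for repeat tracts.
    """
    cds = cds.upper()
    v = variant
    if v.kind == "deletion" or v.kind == "duplication":
        _check_bounds(cds, v)
        s, e = v.start, v.end
        while e < len(cds) and cds[e] == cds[s - 1]:
            s += 1
            e += 1
        if (s, e) != (v.start, v.end):
            v = replace(v, start=s, end=e,
                        ref_bases=cds[s - 1 : e] if v.ref_bases is not None else None,
                        raw="")
        return v
    if v.kind == "insertion":
        _check_bounds(cds, v)
        p, alt = v.start, v.alt_bases
        while p < len(cds) - 1 and cds[p] == alt[0]:
            alt = alt[1:] + alt[0]
            p += 1
        if p != v.start:
            v = replace(v, start=p, end=p + 1, alt_bases=alt, raw="")
        return v
    return v


def translate(cds: str) -> tuple[str, bool]:
    """Standard-code translation up to (excluding) the first stop codon.

    Returns ``(protein, stop_reached)``.  A trailing incomplete codon is
    ignored; non-ACGT characters raise.
    """
    cds = cds.upper()
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValidationError(f"non-ACGT characters in sequence: {sorted(bad)}")
    if len(cds) < 3:
        raise ValidationError("sequence shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, False
    return aa[:stop], True


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect of a coding variant.

    ``residue`` is the first affected residue; for frameshifts,
    ``fs_stop_distance`` is the position of the new stop counting the first
    altered residue as 1 (the N of ``fsTerN``/``fsXN``).
    """

    category: str
    residue: Optional[int] = None
    ref_aa: Optional[str] = None  # one-letter
    alt_aa: Optional[str] = None
    fs_stop_distance: Optional[int] = None
    end_residue: Optional[int] = None  # last residue of an affected span
    end_ref_aa: Optional[str] = None
    inserted: Optional[str] = None  # one-letter sequence for ins/delins

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown consequence category {self.category!r}")
        if (self.fs_stop_distance is not None) != (self.category == "frameshift"):
            raise ValidationError("fs_stop_distance present iff category is frameshift")

    @property
    def hgvs_p(self) -> str:
        return format_hgvs_p(self)


def _aa3(aa: Optional[str]) -> str:
    return AA3.get(aa or "", "Xaa")


def _seq3(seq: str) -> str:
    return "".join(AA3.get(a, "Xaa") for a in seq)


def format_hgvs_p(consequence: ProteinConsequence, dialect: str = "paper") -> str:
    """Three-letter HGVS ``p.`` name in the requested dialect.

    ``dialect="paper"`` writes stops as ``X`` and frameshifts as ``fsXN``
    (the legacy clinical style, e.g. ``p.Tyr292X``, ``p.Asp409GlyfsX95``);
    ``dialect="hgvs"`` writes ``Ter``/``fsTerN``.
    """
    if dialect not in ("paper", "hgvs"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    ter = "X" if dialect == "paper" else "Ter"
    c = consequence
    cat = c.category

    if cat == "synonymous":
        return "p.(=)"
    if cat in ("splice_canonical", "intronic"):
        return "p.?"
    if cat == "start_loss":
        return "p.Met1?"
    if cat == "stop_loss":
        return f"p.{ter}{c.residue}ext?"
    if cat == "nonsense":
        return f"p.{_aa3(c.ref_aa)}{c.residue}{ter}"
    if cat == "missense":
        if c.end_residue is not None and c.end_residue != c.residue:
            return (
                f"p.{_aa3(c.ref_aa)}{c.residue}_{_aa3(c.end_ref_aa)}{c.end_residue}"
                f"delins{_seq3(c.inserted or '')}"
            )
        return f"p.{_aa3(c.ref_aa)}{c.residue}{_aa3(c.alt_aa)}"
    if cat == "frameshift":
        return f"p.{_aa3(c.ref_aa)}{c.residue}{_aa3(c.alt_aa)}fs{ter}{c.fs_stop_distance}"
    if cat == "no_stop_found_frameshift":
        return f"p.{_aa3(c.ref_aa)}{c.residue}{_aa3(c.alt_aa)}fs{ter}?"
    if cat == "inframe_deletion":
        if c.inserted:
            span = (
                f"{_aa3(c.ref_aa)}{c.residue}"
                if c.end_residue in (None, c.residue)
                else f"{_aa3(c.ref_aa)}{c.residue}_{_aa3(c.end_ref_aa)}{c.end_residue}"
            )
            return f"p.{span}delins{_seq3(c.inserted)}"
        if c.end_residue in (None, c.residue):
            return f"p.{_aa3(c.ref_aa)}{c.residue}del"
        return f"p.{_aa3(c.ref_aa)}{c.residue}_{_aa3(c.end_ref_aa)}{c.end_residue}del"
    if cat == "inframe_insertion":
        if c.inserted and c.end_residue is not None and c.end_residue != c.residue:
            if c.ref_aa is None:
                return f"p.?ins{_seq3(c.inserted)}"
            return (
                f"p.{_aa3(c.ref_aa)}{c.residue}_{_aa3(c.end_ref_aa)}{c.end_residue}"
                f"ins{_seq3(c.inserted)}"
            )
        return f"p.{_aa3(c.ref_aa)}{c.residue}delins{_seq3(c.inserted or '')}"
    raise AssertionError(cat)


def _first_difference(a: str, b: str) -> int:
    """0-based index of the first position where two strings differ."""
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def derive_consequence(cds: str, variant: CodingVariant) -> ProteinConsequence:
    """Derive the protein-level effect of a variant on a coding sequence.

    Canonical-splice-site variants (intron offset ±1/±2) return
    ``splice_canonical`` with no protein prediction; deeper intronic ones
    return ``intronic``.  Exonic variants are 3'-normalized, applied, and the
    wild-type and mutant translations compared codon by codon.  A frameshift
    whose first altered codon is itself a stop is reported as nonsense, per
    HGVS; a frameshift never reaching a stop within the supplied CDS is
    reported as ``no_stop_found_frameshift``.
    """
    if variant.intron_offset is not None:
        cat = "splice_canonical" if abs(variant.intron_offset) <= 2 else "intronic"
        return ProteinConsequence(category=cat)

    nv = normalize_3prime(cds, variant)
    mutant = apply_variant(cds, nv)
    wt_aa, wt_stop = translate(cds)
    mt_aa, mt_stop = translate(mutant)
    wt_full = wt_aa + ("*" if wt_stop else "")
    mt_full = mt_aa + ("*" if mt_stop else "")

    if wt_full == mt_full:
        return ProteinConsequence(category="synonymous")

    i = _first_difference(wt_full, mt_full)
    res = i + 1
    wt_at = wt_full[i] if i < len(wt_full) else None
    mt_at = mt_full[i] if i < len(mt_full) else None
    delta = len(mutant) - len(cds)

    if res == 1 and wt_full[:1] == "M" and mt_at != "M":
        return ProteinConsequence(category="start_loss", residue=1, ref_aa="M", alt_aa=mt_at)

    if delta % 3 != 0:
        if mt_at == "*":
            return ProteinConsequence(category="nonsense", residue=res, ref_aa=wt_at, alt_aa="*")
        if not mt_stop:
            return ProteinConsequence(
                category="no_stop_found_frameshift", residue=res, ref_aa=wt_at, alt_aa=mt_at
            )
        return ProteinConsequence(
            category="frameshift", residue=res, ref_aa=wt_at, alt_aa=mt_at,
            fs_stop_distance=len(mt_aa) - i + 1,
        )

    if wt_at == "*":
        # Variant removes or outruns the stop codon.
        return ProteinConsequence(category="stop_loss", residue=res, ref_aa="*", alt_aa=mt_at)
    if mt_at == "*":
        return ProteinConsequence(category="nonsense", residue=res, ref_aa=wt_at, alt_aa="*")

    if delta == 0:
        if len(wt_full) == len(mt_full):
            j = len(wt_full) - 1
            while j > i and wt_full[j] == mt_full[j]:
                j -= 1
            if j == i:
                return ProteinConsequence(
                    category="missense", residue=res, ref_aa=wt_at, alt_aa=mt_at
                )
            # multi-residue same-length replacement (delins at protein level)
            return ProteinConsequence(
                category="missense", residue=res, ref_aa=wt_at,
                end_residue=j + 1, end_ref_aa=wt_full[j], inserted=mt_full[i : j + 1],
            )
        # same DNA length but translations diverge in length (stop shifted)
        return ProteinConsequence(category="missense", residue=res, ref_aa=wt_at, alt_aa=mt_at)

    prot_delta = len(mt_aa) - len(wt_aa)
    if prot_delta < 0:
        k = -prot_delta
        if i + k <= len(wt_aa) and wt_aa[i + k :] == mt_aa[i:]:
            return ProteinConsequence(
                category="inframe_deletion", residue=res, ref_aa=wt_aa[i],
                end_residue=i + k, end_ref_aa=wt_aa[i + k - 1],
            )
        # deletion plus substitution: delins naming over the changed span
        s = 0
        while s < min(len(wt_aa), len(mt_aa)) - i and wt_aa[-1 - s] == mt_aa[-1 - s]:
            s += 1
        return ProteinConsequence(
            category="inframe_deletion", residue=res, ref_aa=wt_aa[i],
            end_residue=len(wt_aa) - s, end_ref_aa=wt_aa[len(wt_aa) - s - 1],
            inserted=mt_aa[i : len(mt_aa) - s],
        )
    else:
        k = prot_delta
        if i + k <= len(mt_aa) and mt_aa[i + k :] == wt_aa[i:]:
            if i == 0:
                return ProteinConsequence(
                    category="inframe_insertion", residue=1, inserted=mt_aa[:k], end_residue=1 + k
                )
            return ProteinConsequence(
                category="inframe_insertion", residue=i, ref_aa=wt_aa[i - 1],
                end_residue=i + 1, end_ref_aa=wt_aa[i], inserted=mt_aa[i : i + k],
            )
        s = 0
        while s < min(len(wt_aa), len(mt_aa)) - i and wt_aa[-1 - s] == mt_aa[-1 - s]:
            s += 1
        return ProteinConsequence(
            category="inframe_insertion", residue=res, ref_aa=wt_aa[i],
            end_residue=max(res, len(wt_aa) - s), end_ref_aa=wt_aa[max(i, len(wt_aa) - s - 1)],
            inserted=mt_aa[i : len(mt_aa) - s],
        )
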