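"""Restriction-site gain/loss detection for PCR-RFLP genotyping design.

A point mutation that creates (or destroys) a recognition site lets a
diagnostic lab confirm the genotype by digesting a PCR product instead of
re-sequencing — the classic design for following a family-specific GAA
allele (BfaI for c.876C>G, SfcI for c.1895T>G).  Recognition sequences may
use IUPAC degenerate codes (SfcI = CTRYAG); both strands are scanned and
positions are reported on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .hgvs import CodingVariant, apply_variant

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction enzyme: name plus IUPAC recognition sequence."""

    name: str
    site: str

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise ValidationError(f"{self.name}: recognition site shorter than 4 bases")
        bad = set(site) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")

    @property
    def reverse_complement_site(self) -> str:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(self.site))

    @property
    def palindromic(self) -> bool:
        return self.site == self.reverse_complement_site


BFAI = EnzymeDef("BfaI", "CTAG")
SFCI = EnzymeDef("SfcI", "CTRYAG")
DEFAULT_ENZYMES = (BFAI, SFCI)


def iupac_match(site: str, window: str) -> bool:
    """True iff every window base lies in the degeneracy set of the site code."""
    if len(site) != len(window):
        raise ValidationError(
            f"site length {len(site)} != window length {len(window)}"
        )
    for code, base in zip(site.upper(), window.upper()):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValidationError(f"invalid IUPAC code {code!r} in site") from None
        if base not in allowed:
            if base not in IUPAC_SETS:
                raise ValidationError(f"invalid base {base!r} in window")
            return False
    return True


def find_sites(sequence: str, enzyme: EnzymeDef, both_strands: bool = True) -> list[int]:
    """All 1-based forward-strand start positions of the recognition site.

    Matches of the reverse-complement site are reported at their
    forward-strand start; duplicates from palindromic sites collapse.
    """
    seq = sequence.upper()
    patterns = {enzyme.site}
    if both_strands:
        patterns.add(enzyme.reverse_complement_site)
    width = len(enzyme.site)
    hits: set[int] = set()
    for start in range(len(seq) - width + 1):
        window = seq[start : start + width]
        if any(iupac_match(p, window) for p in patterns):
            hits.add(start + 1)
    return sorted(hits)


def site_diff(
    wild_cds: str,
    variant: CodingVariant,
    enzymes: tuple[EnzymeDef, ...] = DEFAULT_ENZYMES,
) -> dict[str, dict[str, list[int]]]:
    """Per-enzyme recognition sites gained and lost by a variant.

    ``gained`` positions are mutant-sequence coordinates, ``lost`` positions
    wild-type coordinates.  Sites straddling the window edge of the supplied
    sequence cannot be seen.
    """
    mutant = apply_variant(wild_cds, variant)
    out: dict[str, dict[str, list[int]]] = {}
    for enzyme in enzymes:
        wt = set(find_sites(wild_cds, enzyme))
        mt = set(find_sites(mutant, enzyme))
        out[enzyme.name] = {
            "gained": sorted(mt - wt),
            "lost": sorted(wt - mt),
        }
    return out
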