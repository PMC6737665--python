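"""Brute-force reference implementations used only to check the package.

Deliberately independent of pompevar internals: its own genetic-code table,
its own string editing, and a naive codon-by-codon comparison of the full
translations.  Kept simple rather than fast.
"""

from __future__ import annotations

# Standard genetic code, written out by hand.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> tuple[str, bool]:
    """Translate codon by codon up to (excluding) the first stop."""
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = GENETIC_CODE[seq[i : i + 3]]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def oracle_apply(seq: str, variant) -> str:
    """Edit the sequence by plain slicing, without any normalization."""
    s, e = variant.start, variant.end
    if variant.kind == "substitution":
        assert seq[s - 1] == variant.ref_bases
        return seq[: s - 1] + variant.alt_bases + seq[s:]
    if variant.kind == "deletion":
        return seq[: s - 1] + seq[e:]
    if variant.kind == "insertion":
        return seq[:s] + variant.alt_bases + seq[s:]
    if variant.kind == "duplication":
        return seq[:e] + seq[s - 1 : e] + seq[e:]
    if variant.kind == "delins":
        return seq[: s - 1] + variant.alt_bases + seq[e:]
    raise AssertionError(variant.kind)


def oracle_consequence(cds: str, variant) -> dict:
    """Category, first affected residue, and fs stop distance, from scratch.

    Returns a dict so the test can compare field by field against the
    engine's ProteinConsequence.
    """
    mutant = oracle_apply(cds, variant)
    wt_aa, wt_stop = oracle_translate(cds)
    mt_aa, mt_stop = oracle_translate(mutant)
    wt_full = wt_aa + ("*" if wt_stop else "")
    mt_full = mt_aa + ("*" if mt_stop else "")

    if wt_full == mt_full:
        return {"category": "synonymous", "residue": None, "fs_stop_distance": None}

    i = 0
    limit = min(len(wt_full), len(mt_full))
    while i < limit and wt_full[i] == mt_full[i]:
        i += 1
    res = i + 1
    wt_at = wt_full[i] if i < len(wt_full) else None
    mt_at = mt_full[i] if i < len(mt_full) else None
    delta = len(mutant) - len(cds)

    if res == 1 and wt_full[:1] == "M" and mt_at != "M":
        return {"category": "start_loss", "residue": 1, "fs_stop_distance": None}

    if delta % 3 != 0:
        if mt_at == "*":
            return {"category": "nonsense", "residue": res, "fs_stop_distance": None}
        if not mt_stop:
            return {"category": "no_stop_found_frameshift", "residue": res, "fs_stop_distance": None}
        stop_residue = len(mt_aa) + 1
        return {"category": "frameshift", "residue": res, "fs_stop_distance": stop_residue - res + 1}

    if wt_at == "*":
        return {"category": "stop_loss", "residue": res, "fs_stop_distance": None}
    if mt_at == "*":
        return {"category": "nonsense", "residue": res, "fs_stop_distance": None}
    if delta == 0:
        return {"category": "missense", "residue": res, "fs_stop_distance": None}
    category = "inframe_deletion" if len(mt_aa) < len(wt_aa) else "inframe_insertion"
    return {"category": category, "residue": res, "fs_stop_distance": None}
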