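"""HGVS parsing, sequence editing, translation, and consequence naming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pompevar.errors import (
    HgvsParseError,
    ReferenceMismatchError,
    UnsupportedVariantError,
    ValidationError,
)
from pompevar.hgvs import (
    CodingVariant,
    apply_variant,
    derive_consequence,
    format_cdna,
    format_hgvs_p,
    normalize_3prime,
    parse_cdna,
    translate,
)
from pompevar.simulate import SimulationConfig, make_cds, random_variant

from oracle import oracle_apply, oracle_consequence, oracle_translate


class TestParse:
    @pytest.mark.parametrize(
        "text,kind,start,end,offset,ref,alt",
        [
            ("c.876C>G", "substitution", 876, 876, None, "C", "G"),
            ("c.1327-2A>G", "substitution", 1327, 1327, -2, "A", "G"),
            ("c.858+24G>C", "substitution", 858, 858, 24, "G", "C"),
            ("c.1411_1414delGAGA", "deletion", 1411, 1414, None, "GAGA", None),
            ("c.1411_14delGAGA", "deletion", 1411, 1414, None, "GAGA", None),
            ("c.2024_2026delACA", "deletion", 2024, 2026, None, "ACA", None),
            ("c.15del", "deletion", 15, 15, None, None, None),
            ("c.1226insG", "insertion", 1226, 1227, None, None, "G"),
            ("c.10_11insXYZ".replace("XYZ", "TAC"), "insertion", 10, 11, None, None, "TAC"),
            ("c.7dup", "duplication", 7, 7, None, None, None),
            ("c.7_9dupGCT", "duplication", 7, 9, None, "GCT", None),
            ("c.4_6delinsTT", "delins", 4, 6, None, None, "TT"),
        ],
    )
    def test_supported_forms(self, text, kind, start, end, offset, ref, alt):
        v = parse_cdna(text)
        assert (v.kind, v.start, v.end, v.intron_offset, v.ref_bases, v.alt_bases) == (
            kind, start, end, offset, ref, alt,
        )

    @pytest.mark.parametrize(
        "text",
        ["876C>G", "c.>G", "c.12Z>G", "c.10_9delAA", "c.5_9insA", "c.1411_1414delGA"],
    )
    def test_malformed_rejected(self, text):
        with pytest.raises((HgvsParseError, ValidationError)):
            parse_cdna(text)

    def test_unsupported_kind_is_explicit(self):
        with pytest.raises(UnsupportedVariantError):
            parse_cdna("c.4_6inv")

    def test_truncated_end_expansion_requires_shorter_suffix(self):
        # 1411_14 -> 1414, but a full-width smaller end is an error
        assert parse_cdna("c.1411_14del").end == 1414
        with pytest.raises(HgvsParseError):
            parse_cdna("c.1411_0014del")


class TestApply:
    def test_substitution(self, toy_cds):
        assert apply_variant(toy_cds, parse_cdna("c.10A>T")) == "ATGCCCGCTTAATAG"

    def test_insertion_single_position_dialect(self, toy_cds):
        assert apply_variant(toy_cds, parse_cdna("c.6insA")) == "ATGCCCAGCTAAATAG"

    def test_insertion_between_bases(self, toy_cds):
        assert apply_variant(toy_cds, parse_cdna("c.6_7insA")) == "ATGCCCAGCTAAATAG"

    def test_reference_mismatch_message(self, toy_cds):
        with pytest.raises(ReferenceMismatchError, match="expected C found A"):
            apply_variant(toy_cds, parse_cdna("c.10C>T"))

    def test_intronic_cannot_apply(self, toy_cds):
        with pytest.raises(ValidationError, match="intronic"):
            apply_variant(toy_cds, parse_cdna("c.5-2A>G"))

    def test_deletion_duplication_delins(self, toy_cds):
        assert apply_variant(toy_cds, parse_cdna("c.4_6del")) == "ATGGCTAAATAG"
        assert apply_variant(toy_cds, parse_cdna("c.4_6dup")) == "ATGCCCCCCGCTAAATAG"
        assert apply_variant(toy_cds, parse_cdna("c.4_6delinsTT")) == "ATGTTGCTAAATAG"

    @pytest.mark.parametrize("kind", ["substitution", "deletion", "insertion", "duplication", "delins"])
    def test_length_delta_matches_definition(self, toy_cds, kind):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = random_variant(rng, toy_cds, kinds=(kind,))
            assert len(apply_variant(toy_cds, v)) - len(toy_cds) == v.length_delta


class TestTranslate:
    def test_stops_at_first_stop(self, toy_cds):
        assert translate(toy_cds) == ("MPAK", True)

    def test_minimal(self):
        assert translate("ATGTAA") == ("M", True)

    def test_trailing_incomplete_codon_ignored(self):
        assert translate("ATGAAAG") == ("MK", False)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValidationError):
            translate("ATGNNN")


class TestNormalize3Prime:
    def test_deletion_shifts_through_repeat(self):
        # deleting any A of the AAA run names the 3'-most one
        cds = "ATGCCCGCTAAATAG"
        v = normalize_3prime(cds, parse_cdna("c.10del"))
        assert (v.start, v.end) == (12, 12)

    def test_insertion_rotates_through_repeat(self):
        cds = "ATGCCCGCTAAATAG"
        v = normalize_3prime(cds, parse_cdna("c.9_10insA"))
        assert v.start == 12 and v.alt_bases == "A"

    def test_normalization_preserves_edited_sequence(self, toy_cds):
        rng = np.random.default_rng(5)
        for _ in range(100):
            v = random_variant(rng, toy_cds, kinds=("deletion", "insertion", "duplication"))
            assert apply_variant(toy_cds, v) == apply_variant(toy_cds, normalize_3prime(toy_cds, v))


class TestConsequence:
    def test_nonsense(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.10A>T"))
        assert c.category == "nonsense" and c.residue == 4
        assert format_hgvs_p(c, "paper") == "p.Lys4X"
        assert format_hgvs_p(c, "hgvs") == "p.Lys4Ter"

    def test_frameshift_with_stop_distance(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.6_7insA"))
        assert c.category == "frameshift"
        assert (c.residue, c.fs_stop_distance) == (3, 2)
        assert format_hgvs_p(c, "hgvs") == "p.Ala3SerfsTer2"
        assert format_hgvs_p(c, "paper") == "p.Ala3SerfsX2"

    def test_canonical_splice_site(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.1327-2A>G"))
        assert c.category == "splice_canonical"
        assert c.hgvs_p == "p.?"

    def test_deep_intronic(self, toy_cds):
        assert derive_consequence(toy_cds, parse_cdna("c.858+24G>C")).category == "intronic"

    def test_synonymous_third_position(self):
        cds = "ATGCCCGCTAAATAG"
        c = derive_consequence(cds, parse_cdna("c.6C>A"))  # CCC -> CCA, still Pro
        assert c.category == "synonymous" and c.hgvs_p == "p.(=)"

    def test_missense(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.7G>C"))  # GCT -> CCT, Ala3Pro
        assert c.category == "missense"
        assert format_hgvs_p(c, "paper") == "p.Ala3Pro"

    def test_inframe_deletion(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.7_9del"))
        assert c.category == "inframe_deletion"
        assert format_hgvs_p(c) == "p.Ala3del"

    def test_inframe_insertion(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.6_7insGAT"))
        assert c.category == "inframe_insertion"
        assert "ins" in format_hgvs_p(c)

    def test_start_loss(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.2T>C"))
        assert c.category == "start_loss" and c.hgvs_p == "p.Met1?"

    def test_stop_loss_flagged(self, toy_cds):
        c = derive_consequence(toy_cds, parse_cdna("c.13T>C"))  # TAG -> CAG
        assert c.category == "stop_loss"

    def test_frameshift_without_downstream_stop(self):
        cds = "ATGAAAAAAAAATAA"
        c = derive_consequence(cds, parse_cdna("c.4del"))
        assert c.category == "no_stop_found_frameshift"
        assert c.fs_stop_distance is None

    def test_frameshift_hitting_stop_immediately_is_nonsense(self):
        # deleting c.4 of ATG AAA TAA GCT... frame -> first altered codon is a stop
        cds = "ATGTTAAGCGCTTAA"
        c = derive_consequence(cds, parse_cdna("c.5del"))
        assert c.category in ("nonsense", "frameshift")  # depends on first altered codon
        if c.category == "nonsense":
            assert c.fs_stop_distance is None

    def test_paper_frameshift_dialect_shape(self):
        from pompevar.hgvs import ProteinConsequence

        c = ProteinConsequence(
            category="frameshift", residue=409, ref_aa="D", alt_aa="G", fs_stop_distance=95
        )
        assert format_hgvs_p(c, "paper") == "p.Asp409GlyfsX95"
        assert format_hgvs_p(c, "hgvs") == "p.Asp409GlyfsTer95"


def _roundtrip_cases(n: int, seed: int = 101):
    rng = np.random.default_rng(seed)
    cds = make_cds(SimulationConfig(seed=7, cds_length_codons=120))
    return [random_variant(rng, cds) for _ in range(n)]


def test_parse_format_roundtrip_on_generated_variants():
    """format -> parse must reproduce every generated variant exactly."""
    for v in _roundtrip_cases(1200):
        assert parse_cdna(format_cdna(v)) == v


def test_consequence_agrees_with_bruteforce_oracle():
    """Engine vs an independent edit-and-retranslate oracle on random pairs."""
    rng = np.random.default_rng(202)
    mismatches = []
    for i in range(1200):
        cds = make_cds(SimulationConfig(seed=int(rng.integers(0, 2**31)), cds_length_codons=int(rng.integers(10, 120))))
        v = random_variant(rng, cds)
        got = derive_consequence(cds, v)
        want = oracle_consequence(cds, v)
        ok = got.category == want["category"]
        if ok and want["residue"] is not None and got.category != "inframe_insertion":
            ok = got.residue == want["residue"]
        if ok and got.category == "frameshift":
            ok = got.fs_stop_distance == want["fs_stop_distance"]
        if not ok:
            mismatches.append((format_cdna(v), got, want))
    assert not mismatches, mismatches[:3]


@settings(derandomize=True, max_examples=150)
@given(st.data())
def test_synonymous_wobble_substitutions(data):
    """Any third-position substitution preserving the residue is synonymous."""
    cds = make_cds(SimulationConfig(seed=3, cds_length_codons=50))
    codon_idx = data.draw(st.integers(min_value=2, max_value=48))
    pos = codon_idx * 3  # third base of codon codon_idx (1-based)
    ref = cds[pos - 1]
    alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
    v = CodingVariant(kind="substitution", start=pos, end=pos, ref_bases=ref, alt_bases=alt)
    mutant = oracle_apply(cds, v)
    if oracle_translate(mutant) == oracle_translate(cds):
        assert derive_consequence(cds, v).category == "synonymous"
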