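"""Activity normalization and the A-F severity classifier."""

import numpy as np
import pytest

from pompevar.errors import ValidationError
from pompevar.severity import (
    AssayRecord,
    BandCode,
    NormalizedActivity,
    WesternProfile,
    band_meets,
    classify_severity,
    normalize_activity,
    rate_assay_table,
    round_report,
)


def profile(m110, c110, c95, c76):
    return WesternProfile.from_strings(m110, c110, c95, c76)


WT = AssayRecord.from_values("WT", 60.5, 631.3, profile("4,4", "4,4", "4,4", "4,4"))


class TestBandCode:
    def test_parse_and_str_roundtrip(self):
        assert str(BandCode.from_string("2,4")) == "2,4"

    @pytest.mark.parametrize("text", ["6,4", "2,5", "0,4", "24", "a,b"])
    def test_invalid_codes_rejected(self, text):
        with pytest.raises(ValidationError):
            BandCode.from_string(text)


class TestBandMeets:
    @pytest.mark.parametrize(
        "code,threshold,expected",
        [
            ((2, 4), (2, 4), True),
            ((3, 4), (4, 4), False),
            ((2, 2), (2, 4), False),  # wrong apparent mass never meets
            ((5, 4), (2, 4), True),
            ((1, 1), (1, 1), True),  # floor threshold met by anything
            ((4, 2), (1, 1), True),
        ],
    )
    def test_threshold_semantics(self, code, threshold, expected):
        assert band_meets(BandCode(*code), BandCode(*threshold)) is expected


class TestNormalization:
    def test_medium_percent_reproduces_published_value(self):
        mut = AssayRecord.from_values("m", 3.31, 478.3, profile("3,4", "4,4", "4,4", "4,4"))
        norm = normalize_activity(mut, WT)
        assert norm.m_report == 5.47
        assert norm.c_report == 75.8

    def test_low_cell_activities_round_to_two_decimals(self):
        norm = normalize_activity(
            AssayRecord.from_values("m", 0, 4.8, profile("1,1", "3,4", "2,4", "2,4")), WT
        )
        assert norm.c_report == 0.76
        norm = normalize_activity(
            AssayRecord.from_values("m", 0.05, 0.1, profile("1,1", "3,4", "2,4", "2,4")), WT
        )
        assert (norm.m_report, norm.c_report) == (0.08, 0.02)

    def test_self_normalization_is_exactly_100(self):
        norm = normalize_activity(WT, WT)
        assert (norm.m_percent, norm.c_percent) == (100.0, 100.0)

    def test_zero_wildtype_rejected(self):
        zero = AssayRecord.from_values("wt0", 0, 0, profile("4,4", "4,4", "4,4", "4,4"))
        with pytest.raises(ValidationError, match="positive"):
            normalize_activity(WT, zero)

    def test_replicates_are_averaged(self):
        rec = AssayRecord.from_values("m", [1.0, 3.0], [10.0, 30.0], profile("4,4", "4,4", "4,4", "4,4"))
        assert (rec.medium_activity, rec.cell_activity) == (2.0, 20.0)

    def test_half_up_reporting(self):
        assert round_report(32.35) == 32.4
        assert round_report(5.475) == 5.48
        assert round_report(9.999) == 10.0


class TestClassifier:
    def test_no_protein_no_activity_is_class_a(self):
        res = classify_severity(NormalizedActivity(0, 0), profile("1,1", "1,1", "1,1", "1,1"))
        assert res.classes == ("A",) and not res.ambiguous

    def test_retained_intracellular_precursor_is_class_b(self):
        res = classify_severity(NormalizedActivity(0, 0), profile("1,1", "2,4", "2,4", "2,4"))
        assert res.classes == ("B",)

    def test_wildtype_like_is_class_f(self):
        res = classify_severity(NormalizedActivity(100, 100), profile("4,4", "4,4", "4,4", "4,4"))
        assert res.classes == ("F",)

    def test_discordant_compartments_give_ambiguous_pair(self):
        # medium at class-D level, lysate at class-F level, secretion reduced
        res = classify_severity(NormalizedActivity(5.47, 75.77), profile("3,4", "4,4", "4,4", "4,4"))
        assert res.classes == ("D", "E") and res.ambiguous

    def test_most_severe_rule_wins_on_overlap(self):
        # C%=4 lies in both the B (0-5) and C (2-10) ranges; B wins at M%<=2
        res = classify_severity(NormalizedActivity(1, 4), profile("1,1", "2,4", "2,4", "2,4"))
        assert res.classes == ("B",)

    def test_class_c_band_requirements(self):
        res = classify_severity(NormalizedActivity(6, 6), profile("1,1", "2,4", "2,4", "2,4"))
        assert res.classes == ("C",)

    def test_class_d_and_e(self):
        assert classify_severity(
            NormalizedActivity(15, 15), profile("2,4", "3,4", "3,4", "3,4")
        ).classes == ("D",)
        assert classify_severity(
            NormalizedActivity(45, 45), profile("3,4", "4,4", "4,4", "4,4")
        ).classes == ("E",)

    def test_totality_over_activity_grid_and_band_samples(self):
        grid = [0, 1, 2, 2.5, 5, 5.5, 10, 20, 30, 45, 60, 75, 100]
        rng = np.random.default_rng(42)
        codes = [(q, u) for q in range(1, 6) for u in range(1, 5)]
        for m in grid:
            for c in grid:
                for _ in range(8):
                    bands = [codes[i] for i in rng.integers(0, len(codes), size=4)]
                    prof = WesternProfile(*(BandCode(*b) for b in bands))
                    res = classify_severity(NormalizedActivity(m, c), prof)
                    assert 1 <= len(res.classes) <= 2
                    assert all(cls in "ABCDEF" for cls in res.classes)

    def test_severity_monotone_in_activity_with_normal_bands(self):
        prof = profile("4,4", "4,4", "4,4", "4,4")
        order = "ABCDEF"
        last = 0
        for x in [0, 1, 2, 3, 5, 8, 12, 20, 30, 40, 55, 65, 80, 100]:
            res = classify_severity(NormalizedActivity(x, x), prof)
            assert not res.ambiguous
            rank = order.index(res.classes[0])
            assert rank >= last
            last = rank

    def test_concordant_templates_are_never_ambiguous(self):
        from pompevar.simulate import DEFAULT_CLASS_TEMPLATES, template_profile

        for cls, (m, c, bands) in DEFAULT_CLASS_TEMPLATES.items():
            res = classify_severity(NormalizedActivity(m, c), template_profile(bands))
            assert res.classes == (cls,) and not res.ambiguous


class TestRateTable:
    def test_published_assay_table_reproduced(self, assay_records):
        rated = {r.variant_label: r for r in rate_assay_table(assay_records, "Wild type")}
        assert rated["Wild type"].class_string == "-"
        assert rated["p.Tyr292X"].result.classes == ("B",)
        assert rated["p.Asp513Gly"].result.classes == ("B",)
        assert rated["p.Leu632Arg"].result.classes == ("B",)
        assert rated["p.Ala261Thr"].result.classes == ("D", "E")
        assert rated["p.Ala261Thr"].class_string == "D/E"

    def test_wildtype_only_table_yields_reference_row_only(self):
        rated = rate_assay_table([WT], "WT")
        assert len(rated) == 1 and rated[0].result is None

    def test_duplicate_wildtype_rejected(self):
        with pytest.raises(ValidationError, match="exactly one"):
            rate_assay_table([WT, WT], "WT")

    def test_missing_wildtype_rejected(self):
        with pytest.raises(ValidationError):
            rate_assay_table([WT], "nope")
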