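"""Transfection-assay normalization and the A-F variant severity rating.

A GAA variant expressed in COS-7 cells yields two enzyme activities
(culture medium and cell lysate, nmol 4-MU/hr/mg protein) and four western
band scores for the secreted 110 kDa precursor (M110) and the intracellular
110 kDa precursor, 95 kDa intermediate, and 76 kDa mature forms (C110, C95,
C76).  Activities are expressed as percent of the wild-type construct
(M%Wt, C%Wt); the rating combines percentages and band scores into classes
A (very severe, no protein — a CRIM-negative surrogate) through
F (nonpathogenic).

Band scores are two digits: quantity 1-5 (not detectable … clearly more
than normal) and quality 1-4, where 4 means the apparent molecular mass is
normal.  A band threshold like ">= 2,4" is met only by a band of at least
that quantity at the normal mass; the floor threshold (1,1) is met by
anything.

The six class rules are evaluated most-severe-first, which resolves the
overlaps in the printed activity ranges.  When the two compartments are
discordant (e.g. medium at class-D level but lysate at class-F level), each
axis is mapped to the class whose activity range contains it — ties broken
toward the range with the greater lower bound, then toward severity — the
protein evidence caps nonpathogenic calls (A needs absent protein; F needs
all bands normal), and the result is the ambiguous pair, e.g. "D/E".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import fmean
from typing import Iterable, Optional, Sequence, Union

from .errors import ValidationError

CLASSES = ("A", "B", "C", "D", "E", "F")

QUANTITY_MEANING = {
    1: "not detectable",
    2: "barely detectable",
    3: "clearly present, but clearly less than normal",
    4: "normal",
    5: "clearly more than normal",
}
QUALITY_MEANING = {
    1: "too little present to judge",
    2: "apparent molecular mass too low",
    3: "apparent molecular mass too high",
    4: "apparent molecular mass normal",
}


@dataclass(frozen=True)
class BandCode:
    """Two-digit western-blot band score (quantity, quality)."""

    quantity: int
    quality: int

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITY_MEANING:
            raise ValidationError(f"band quantity {self.quantity} not in 1..5")
        if self.quality not in QUALITY_MEANING:
            raise ValidationError(f"band quality {self.quality} not in 1..4")

    @classmethod
    def from_string(cls, text: str) -> "BandCode":
        try:
            q, qual = (int(t) for t in text.strip().split(","))
        except (ValueError, TypeError):
            raise ValidationError(f"band code must look like '2,4', got {text!r}") from None
        return cls(q, qual)

    def __str__(self) -> str:
        return f"{self.quantity},{self.quality}"


ABSENT = BandCode(1, 1)


@dataclass(frozen=True)
class WesternProfile:
    """The four band codes of one expressed construct."""

    m110: BandCode
    c110: BandCode
    c95: BandCode
    c76: BandCode

    @classmethod
    def from_strings(cls, m110: str, c110: str, c95: str, c76: str) -> "WesternProfile":
        return cls(*(BandCode.from_string(t) for t in (m110, c110, c95, c76)))

    @property
    def bands(self) -> tuple[BandCode, BandCode, BandCode, BandCode]:
        return (self.m110, self.c110, self.c95, self.c76)


Activity = Union[float, int, Sequence[float]]


def _mean_activity(value: Activity, label: str) -> float:
    if isinstance(value, (int, float)):
        out = float(value)
    else:
        values = [float(v) for v in value]
        if not values:
            raise ValidationError(f"{label}: empty replicate list")
        out = fmean(values)
    if out < 0:
        raise ValidationError(f"{label}: activity must be non-negative, got {out}")
    return out


@dataclass(frozen=True)
class AssayRecord:
    """One row of a transfection-assay table (replicates are averaged)."""

    variant_label: str
    medium_activity: float
    cell_activity: float
    profile: WesternProfile

    @classmethod
    def from_values(
        cls,
        variant_label: str,
        medium_activity: Activity,
        cell_activity: Activity,
        profile: WesternProfile,
    ) -> "AssayRecord":
        return cls(
            variant_label,
            _mean_activity(medium_activity, f"{variant_label} medium"),
            _mean_activity(cell_activity, f"{variant_label} cells"),
            profile,
        )


@dataclass(frozen=True)
class NormalizedActivity:
    """Percent-of-wild-type activities; unrounded, with report-precision views."""

    m_percent: float
    c_percent: float

    @property
    def m_report(self) -> float:
        return round_report(self.m_percent)

    @property
    def c_report(self) -> float:
        return round_report(self.c_percent)


def round_report(value: float) -> float:
    """Half-up rounding at reporting precision: 2 dp below 10, else 1 dp."""
    d = Decimal(repr(float(value)))
    quantum = Decimal("0.01") if abs(d) < 10 else Decimal("0.1")
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def normalize_activity(mutant: AssayRecord, wildtype: AssayRecord) -> NormalizedActivity:
    """M%Wt and C%Wt: mutant activity as percent of the wild-type construct."""
    if wildtype.medium_activity <= 0 or wildtype.cell_activity <= 0:
        raise ValidationError("wild-type activity must be positive")
    return NormalizedActivity(
        m_percent=100.0 * mutant.medium_activity / wildtype.medium_activity,
        c_percent=100.0 * mutant.cell_activity / wildtype.cell_activity,
    )


def band_meets(code: BandCode, threshold: BandCode) -> bool:
    """A band meets a threshold when quantity suffices at normal mass.

    The floor threshold (1,1) is met by any band; otherwise the band must
    have ``quantity >= threshold.quantity`` and normal apparent mass
    (quality 4).
    """
    if threshold == ABSENT:
        return True
    return code.quantity >= threshold.quantity and code.quality == 4


@dataclass(frozen=True)
class SeverityResult:
    """One or (when compartments disagree) two severity classes."""

    classes: tuple[str, ...]
    ambiguous: bool
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.classes) <= 2:
            raise ValidationError("classes must hold one or two entries")
        if self.ambiguous != (len(self.classes) == 2):
            raise ValidationError("ambiguous iff two classes")

    @property
    def class_string(self) -> str:
        return "/".join(self.classes)


_T = BandCode  # shorthand for thresholds below

# (class, M% range, C% range, thresholds for M110/C110/C95/C76)
_RULES = (
    ("A", (0.0, 2.0), (0.0, 2.0), None),  # additionally: all bands exactly (1,1)
    ("B", (0.0, 2.0), (0.0, 5.0), (_T(1, 1), _T(2, 4), _T(1, 1), _T(1, 1))),
    ("C", (0.0, 10.0), (2.0, 10.0), (_T(1, 1), _T(2, 4), _T(2, 4), _T(2, 4))),
    ("D", (5.0, 30.0), (5.0, 30.0), (_T(2, 4), _T(3, 4), _T(3, 4), _T(3, 4))),
    ("E", (30.0, 60.0), (30.0, 60.0), (_T(2, 4), _T(4, 4), _T(4, 4), _T(4, 4))),
    ("F", (60.0, float("inf")), (60.0, float("inf")), (_T(4, 4), _T(4, 4), _T(4, 4), _T(4, 4))),
)

# Per-axis activity ranges used only for discordant inputs.
_M_RANGES = {cls: m for cls, m, _, _ in _RULES}
_C_RANGES = {cls: c for cls, _, c, _ in _RULES}


def _in_range(x: float, rng: tuple[float, float], cls: str) -> bool:
    lo, hi = rng
    if cls in ("E", "F") or (cls == "C" and rng[0] == 2.0):
        return lo < x <= hi if hi != float("inf") else x > lo
    return lo <= x <= hi


def _bands_ok(profile: WesternProfile, cls: str, thresholds) -> bool:
    if cls == "A":
        return all(b == ABSENT for b in profile.bands)
    return all(band_meets(b, t) for b, t in zip(profile.bands, thresholds))


def _axis_class(x: float, ranges: dict[str, tuple[float, float]]) -> str:
    """Class whose activity range contains x; ties to the most specific range.

    Among the classes whose range contains the value, the one with the
    greatest lower bound wins (a value of 5.5% on the medium axis is rated D,
    whose range starts at 5, rather than C, whose range starts at 0); among
    equal lower bounds, the more severe class wins.
    """
    candidates = [
        cls for cls, rng in ranges.items() if _in_range(x, rng, cls)
    ]
    if not candidates:  # pragma: no cover - ranges jointly cover [0, inf)
        return "F"
    best_lb = max(ranges[c][0] for c in candidates)
    for cls in CLASSES:  # severity order breaks ties
        if cls in candidates and ranges[cls][0] == best_lb:
            return cls
    raise AssertionError


def _band_capped(cls: str, profile: WesternProfile) -> str:
    """Cap an activity-derived class by the protein evidence."""
    if cls == "A" and any(b != ABSENT for b in profile.bands):
        return "B"
    if cls == "F" and not all(band_meets(b, _T(4, 4)) for b in profile.bands):
        return "E"
    return cls


def classify_severity(norm: NormalizedActivity, profile: WesternProfile) -> SeverityResult:
    """Assign the severity class(es) from activities and band codes.

    Rules are tried most-severe-first and the first class whose activity
    ranges and band thresholds all hold wins.  If no rule holds (discordant
    compartments), each axis is rated separately, capped by the band
    evidence, and the pair is returned ambiguous (single class if the two
    coincide after capping).  Classification always uses unrounded
    percentages.
    """
    m, c = norm.m_percent, norm.c_percent
    trace: list[str] = []
    for cls, m_rng, c_rng, thresholds in _RULES:
        m_ok = _in_range(m, m_rng, cls)
        c_ok = _in_range(c, c_rng, cls)
        b_ok = _bands_ok(profile, cls, thresholds)
        trace.append(f"{cls}: M% {'ok' if m_ok else 'no'}, C% {'ok' if c_ok else 'no'}, bands {'ok' if b_ok else 'no'}")
        if m_ok and c_ok and b_ok:
            trace.append(f"matched {cls}")
            return SeverityResult(classes=(cls,), ambiguous=False, rationale=tuple(trace))

    m_cls = _band_capped(_axis_class(m, _M_RANGES), profile)
    c_cls = _band_capped(_axis_class(c, _C_RANGES), profile)
    trace.append(f"discordant: medium axis -> {m_cls}, cell axis -> {c_cls}")
    if m_cls == c_cls:
        return SeverityResult(classes=(m_cls,), ambiguous=False, rationale=tuple(trace))
    pair = tuple(sorted((m_cls, c_cls)))
    return SeverityResult(classes=pair, ambiguous=True, rationale=tuple(trace))


@dataclass(frozen=True)
class RatedVariant:
    variant_label: str
    normalized: NormalizedActivity
    result: Optional[SeverityResult]  # None marks the wild-type reference row

    @property
    def class_string(self) -> str:
        return "-" if self.result is None else self.result.class_string


def rate_assay_table(
    records: Iterable[AssayRecord], wildtype_label: str
) -> list[RatedVariant]:
    """Normalize and classify every non-wild-type record of an assay table.

    Exactly one record must carry the wild-type label; it is reported first
    with 100/100 and a "-" class marker.
    """
    records = list(records)
    wt = [r for r in records if r.variant_label == wildtype_label]
    if len(wt) != 1:
        raise ValidationError(
            f"expected exactly one wild-type record labelled {wildtype_label!r}, found {len(wt)}"
        )
    wildtype = wt[0]
    out = [RatedVariant(wildtype.variant_label, NormalizedActivity(100.0, 100.0), None)]
    for record in records:
        if record is wildtype:
            continue
        norm = normalize_activity(record, wildtype)
        out.append(RatedVariant(record.variant_label, norm, classify_severity(norm, record.profile)))
    return out
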