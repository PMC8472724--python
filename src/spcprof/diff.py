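"""Dual-index label-free differential analysis of average spectral counts.

Two indexes are computed per protein for a pair of conditions X and Y:

* ``DAve = (X - Y) / (X + Y) / 0.5`` — a symmetric fold-change measure in
  [-2, 2]; 0 means no change, |DAve| = 0.4 corresponds to a 1.5-fold
  ratio, +/-2 to presence/absence.
* ``DCI = (X + Y) * (X - Y) / 2`` — a confidence weight that suppresses
  calls backed by few spectra.

A protein is flagged differentially expressed when BOTH |DAve| >= 0.4 and
|DCI| >= 15 (inclusive thresholds, both defaults configurable).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .errors import ValidationError
from .profiling import CohortProfile

DEFAULT_DAVE_THRESHOLD = 0.4
DEFAULT_DCI_THRESHOLD = 15.0

FLAG_UP_X = "up_in_X"
FLAG_UP_Y = "up_in_Y"
FLAG_UNCHANGED = "unchanged"


def dave(x: float, y: float) -> float:
    """Differential-average index 2(x-y)/(x+y); 0 when both are 0."""
    if x < 0 or y < 0:
        raise ValidationError(f"aSpC must be non-negative, got ({x}, {y})")
    total = x + y
    if total == 0:
        return 0.0
    return (x - y) / total / 0.5


def dci(x: float, y: float) -> float:
    """Differential-confidence index (x+y)(x-y)/2."""
    if x < 0 or y < 0:
        raise ValidationError(f"aSpC must be non-negative, got ({x}, {y})")
    return (x + y) * (x - y) / 2.0


@dataclass(frozen=True)
class DiffRecord:
    """One protein's pairwise comparison: indexes and call."""

    protein: str
    x: float
    y: float
    dave: float
    dci: float
    flag: str

    def __post_init__(self) -> None:
        if not (-2.0 - 1e-12 <= self.dave <= 2.0 + 1e-12):
            raise ValidationError(f"DAve out of [-2, 2]: {self.dave}")


@dataclass
class ComparisonReport:
    """All DiffRecords of one pairwise cohort comparison."""

    pair: tuple[str, str]
    records: list[DiffRecord]
    dave_threshold: float
    dci_threshold: float

    @property
    def dep_up_x(self) -> list[DiffRecord]:
        return [r for r in self.records if r.flag == FLAG_UP_X]

    @property
    def dep_up_y(self) -> list[DiffRecord]:
        return [r for r in self.records if r.flag == FLAG_UP_Y]

    @property
    def deps(self) -> set[str]:
        return {r.protein for r in self.records if r.flag != FLAG_UNCHANGED}

    @property
    def n_dep(self) -> int:
        return len(self.deps)


def classify(x: float, y: float, dave_thr: float, dci_thr: float) -> tuple[float, float, str]:
    """Compute both indexes and the dual-threshold call for one protein."""
    d_ave = dave(x, y)
    d_ci = dci(x, y)
    if d_ave >= dave_thr and d_ci >= dci_thr:
        flag = FLAG_UP_X
    elif d_ave <= -dave_thr and d_ci <= -dci_thr:
        flag = FLAG_UP_Y
    else:
        flag = FLAG_UNCHANGED
    return d_ave, d_ci, flag


def compare_pair(
    profile_x: CohortProfile,
    profile_y: CohortProfile,
    dave_thr: float = DEFAULT_DAVE_THRESHOLD,
    dci_thr: float = DEFAULT_DCI_THRESHOLD,
) -> ComparisonReport:
    """Pairwise comparison of two cohort aSpC profiles over their protein union.

    Proteins absent from one profile contribute aSpC 0 on that side. Both
    threshold tests are inclusive (>=).
    """
    if dave_thr < 0 or dci_thr < 0:
        raise ValidationError("thresholds must be non-negative")
    proteins = sorted(set(profile_x.aspc.index) | set(profile_y.aspc.index))
    ax = profile_x.aspc
    ay = profile_y.aspc
    records = []
    for protein in proteins:
        x = float(ax.get(protein, 0.0))
        y = float(ay.get(protein, 0.0))
        if x == 0.0 and y == 0.0:
            continue  # never identified in either condition
        d_ave, d_ci, flag = classify(x, y, dave_thr, dci_thr)
        records.append(DiffRecord(protein, x, y, d_ave, d_ci, flag))
    return ComparisonReport(
        pair=(profile_x.cohort, profile_y.cohort),
        records=records,
        dave_threshold=dave_thr,
        dci_threshold=dci_thr,
    )


def compare_all_pairs(
    profiles: dict[str, CohortProfile],
    pairs: Sequence[tuple[str, str]] = (("He", "Ho"), ("He", "Wt"), ("Wt", "Ho")),
    dave_thr: float = DEFAULT_DAVE_THRESHOLD,
    dci_thr: float = DEFAULT_DCI_THRESHOLD,
) -> list[ComparisonReport]:
    missing = [c for pair in pairs for c in pair if c not in profiles]
    if missing:
        raise ValidationError(f"profiles missing for cohort(s) {sorted(set(missing))}")
    return [compare_pair(profiles[a], profiles[b], dave_thr, dci_thr) for a, b in pairs]


def dep_union(reports: Iterable[ComparisonReport]) -> set[str]:
    """Distinct proteins flagged (either direction) in any report."""
    reports = list(reports)
    if not reports:
        raise ValidationError("dep_union needs at least one report")
    union: set[str] = set()
    for report in reports:
        union |= report.deps
    return union


__all__ = [
    "DEFAULT_DAVE_THRESHOLD",
    "DEFAULT_DCI_THRESHOLD",
    "FLAG_UNCHANGED",
    "FLAG_UP_X",
    "FLAG_UP_Y",
    "ComparisonReport",
    "DiffRecord",
    "classify",
    "compare_all_pairs",
    "compare_pair",
    "dave",
    "dci",
    "dep_union",
]
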