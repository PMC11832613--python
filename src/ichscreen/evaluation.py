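"""Rater-agreement evaluation: 2x2 tables, the standard metric set, and the
two-step independent-rating / adjudication data model.

Performance is scored case-wise on the binary presence of hemorrhage: one
reading is taken as ground truth, the other (a second rater or the
algorithm) is categorized per case as TP/FN/FP/TN, and the standard metrics
follow: SEN, FPR, SPEC, PPV, NPV, ACC and balanced accuracy
(SEN + SPEC) / 2.  Undefined metrics (zero denominator) raise rather than
return NaN — silent NaN propagation would corrupt mean rows.

Summary rows over several comparisons average the counts arithmetically and
the *unrounded* per-comparison metrics (canonical); the average of the
2-decimal rounded metrics is emitted alongside, since published tables are
sometimes assembled that way and both conventions should be inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import (
    AlignmentError,
    CompletenessError,
    ICHScreenError,
    ParameterError,
    RatingsParseError,
    UndefinedMetricError,
)

__all__ = [
    "RatingRecord",
    "ContingencyTable",
    "MetricSet",
    "ComparisonSummary",
    "AdjudicationResult",
    "METRIC_NAMES",
    "round_half_up",
    "build_contingency",
    "compute_metrics",
    "mean_of_comparisons",
    "adjudicate",
    "read_ratings_csv",
    "write_ratings_csv",
]

METRIC_NAMES = ("sen", "fpr", "spec", "ppv", "npv", "acc", "balacc")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding (0.005 -> 0.01), the display convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RatingRecord:
    """One rater's verdict on one case, across the two rating steps.

    ``initial`` is the first independent read; ``revised`` is the optional
    second read after discrepancy review.  The final verdict is the revision
    when present, else the initial; a rater who skipped the case leaves both
    None.
    """

    case_id: str
    rater_id: str
    initial: Optional[int] = None
    revised: Optional[int] = None

    @property
    def final(self) -> Optional[int]:
        return self.revised if self.revised is not None else self.initial


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ParameterError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    sen: float
    fpr: float
    spec: float
    ppv: float
    npv: float
    acc: float
    balacc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.as_dict().items()}


@dataclass
class ComparisonSummary:
    """Mean row over >= 2 comparisons: mean counts plus both metric conventions."""

    mean_counts: dict[str, float]
    mean_metrics: dict[str, float]  # arithmetic mean of unrounded metrics
    mean_metrics_rounded: dict[str, float]  # mean of 2-decimal rounded metrics


@dataclass
class AdjudicationResult:
    finals: dict[str, tuple[int, int]]  # case_id -> (rater1 final, rater2 final)
    discrepancies: list[str]  # cases whose initial verdicts differed
    excluded: list[str]  # cases lacking a final verdict from either rater


def build_contingency(truth: dict[str, int], predicted: dict[str, int]) -> ContingencyTable:
    """2x2 counts of predicted verdicts against ground-truth verdicts."""
    if set(truth) != set(predicted):
        raise AlignmentError(
            f"case sets differ: {sorted(set(truth) ^ set(predicted))[:5]} ..."
        )
    tp = fn = fp = tn = 0
    for case_id, t in truth.items():
        p = predicted[case_id]
        if t is None or p is None:
            raise CompletenessError(f"missing verdict for case {case_id}")
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == 0:
            fn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def compute_metrics(table: ContingencyTable) -> MetricSet:
    """The standard metric set from a 2x2 table.

    sen = tp/(tp+fn), spec = tn/(tn+fp), fpr = fp/(fp+tn) = 1-spec,
    ppv = tp/(tp+fp), npv = tn/(tn+fn), acc = (tp+tn)/n,
    balacc = (sen+spec)/2.
    """

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            raise UndefinedMetricError(name)
        return num / den

    sen = ratio(table.tp, table.tp + table.fn, "sen")
    spec = ratio(table.tn, table.tn + table.fp, "spec")
    return MetricSet(
        sen=sen,
        fpr=ratio(table.fp, table.fp + table.tn, "fpr"),
        spec=spec,
        ppv=ratio(table.tp, table.tp + table.fp, "ppv"),
        npv=ratio(table.tn, table.tn + table.fn, "npv"),
        acc=ratio(table.tp + table.tn, table.n, "acc"),
        balacc=(sen + spec) / 2.0,
    )


def mean_of_comparisons(
    metric_sets: list[MetricSet], tables: list[ContingencyTable]
) -> ComparisonSummary:
    """Mean row over comparisons: arithmetic means of counts and of metrics."""
    if len(metric_sets) < 2 or len(tables) != len(metric_sets):
        raise ParameterError("need >= 2 aligned comparisons to average")
    k = len(tables)
    mean_counts = {
        name: sum(getattr(t, name) for t in tables) / k
        for name in ("tp", "fn", "fp", "tn")
    }
    mean_metrics = {
        name: sum(m.as_dict()[name] for m in metric_sets) / k for name in METRIC_NAMES
    }
    mean_rounded = {
        name: sum(m.rounded()[name] for m in metric_sets) / k for name in METRIC_NAMES
    }
    return ComparisonSummary(
        mean_counts=mean_counts,
        mean_metrics=mean_metrics,
        mean_metrics_rounded=mean_rounded,
    )


def adjudicate(
    ratings_r1: list[RatingRecord], ratings_r2: list[RatingRecord]
) -> AdjudicationResult:
    """Pair the two raters' records; list discrepancies and incomplete cases.

    Cases where the initial verdicts differ form the discrepancy list (these
    are the cases re-evaluated in the second step).  Cases lacking a final
    verdict from either rater are excluded and reported rather than scored.
    """

    def index(records: list[RatingRecord], who: str) -> dict[str, RatingRecord]:
        by_case: dict[str, RatingRecord] = {}
        for rec in records:
            if rec.case_id in by_case:
                raise ICHScreenError(f"duplicate case id {rec.case_id!r} for {who}")
            by_case[rec.case_id] = rec
        return by_case

    idx1 = index(ratings_r1, "rater1")
    idx2 = index(ratings_r2, "rater2")
    if set(idx1) != set(idx2):
        raise AlignmentError("raters cover different case sets")

    finals: dict[str, tuple[int, int]] = {}
    discrepancies: list[str] = []
    excluded: list[str] = []
    for case_id in sorted(idx1):
        r1, r2 = idx1[case_id], idx2[case_id]
        if r1.final is None or r2.final is None:
            excluded.append(case_id)
            continue
        if r1.initial is not None and r2.initial is not None and r1.initial != r2.initial:
            discrepancies.append(case_id)
        finals[case_id] = (r1.final, r2.final)
    return AdjudicationResult(finals=finals, discrepancies=discrepancies, excluded=excluded)


_RATING_COLUMNS = ["case_id", "rater_id", "initial", "revised", "final"]


def write_ratings_csv(records: list[RatingRecord], path) -> Path:
    path = Path(path)
    rows = [
        {
            "case_id": r.case_id,
            "rater_id": r.rater_id,
            "initial": r.initial,
            "revised": r.revised,
            "final": r.final,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RATING_COLUMNS).to_csv(path, index=False)
    return path


def _parse_verdict(value, column: str, line: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        v = int(float(value))
    except (TypeError, ValueError):
        raise RatingsParseError(f"{column} value {value!r} is not a binary verdict", line)
    if v not in (0, 1):
        raise RatingsParseError(f"{column} value {v} is not binary", line)
    return v


def read_ratings_csv(path) -> list[RatingRecord]:
    """Read rating records; enforces final = revised-if-present-else-initial."""
    df = pd.read_csv(path, dtype={"case_id": str, "rater_id": str})
    missing = [c for c in _RATING_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsParseError(f"missing columns {missing}", 1)
    records: list[RatingRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        initial = _parse_verdict(row.initial, "initial", i)
        revised = _parse_verdict(row.revised, "revised", i)
        final = _parse_verdict(row.final, "final", i)
        expected = revised if revised is not None else initial
        if final != expected:
            raise RatingsParseError(
                f"final={final} conflicts with revised/initial (expected {expected})", i
            )
        records.append(
            RatingRecord(
                case_id=str(row.case_id),
                rater_id=str(row.rater_id),
                initial=initial,
                revised=revised,
            )
        )
    return records
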