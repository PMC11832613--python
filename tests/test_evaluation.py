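"""Contingency construction, the standard metric set, mean rows, adjudication."""

import numpy as np
import pytest

from ichscreen.errors import (
    AlignmentError,
    ICHScreenError,
    RatingsParseError,
    UndefinedMetricError,
)
from ichscreen.evaluation import (
    ContingencyTable,
    RatingRecord,
    adjudicate,
    build_contingency,
    compute_metrics,
    mean_of_comparisons,
    read_ratings_csv,
    round_half_up,
    write_ratings_csv,
)


def verdicts_from_counts(tp, fn, fp, tn):
    """Expand a 2x2 table into aligned truth/predicted verdict vectors."""
    truth, pred = {}, {}
    k = 0
    for t, p, count in ((1, 1, tp), (1, 0, fn), (0, 1, fp), (0, 0, tn)):
        for _ in range(count):
            truth[f"c{k}"], pred[f"c{k}"] = t, p
            k += 1
    return truth, pred


class TestBuildContingency:
    def test_enumeration(self):
        truth = {"a": 1, "b": 1, "c": 0, "d": 0}
        pred = {"a": 1, "b": 0, "c": 1, "d": 0}
        t = build_contingency(truth, pred)
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_identity_prediction_has_no_errors(self):
        truth = {f"c{i}": i % 2 for i in range(10)}
        t = build_contingency(truth, dict(truth))
        assert t.fn == 0 and t.fp == 0

    def test_255_case_reconstruction(self):
        truth, pred = verdicts_from_counts(29, 2, 8, 216)
        t = build_contingency(truth, pred)
        assert (t.tp, t.fn, t.fp, t.tn) == (29, 2, 8, 216)
        assert t.n == 255

    def test_case_set_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            build_contingency({"a": 1}, {"b": 1})


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # printed 2-decimal metric rows for the two reader-vs-algorithm comparisons
            ((29, 2, 8, 216), dict(sen=0.94, fpr=0.04, spec=0.96, ppv=0.78,
                                   npv=0.99, acc=0.96, balacc=0.95)),
            ((28, 5, 9, 213), dict(sen=0.85, fpr=0.04, spec=0.96, ppv=0.76,
                                   npv=0.98, acc=0.95, balacc=0.90)),
        ],
    )
    def test_metric_rows_round_to_published_values(self, counts, expected):
        m = compute_metrics(ContingencyTable(*counts))
        assert m.rounded() == expected

    def test_degenerate_all_negative_raises_on_sen(self):
        t = ContingencyTable(0, 0, 0, 10)
        with pytest.raises(UndefinedMetricError) as err:
            compute_metrics(t)
        assert err.value.metric == "sen"

    def test_balacc_identity_and_range(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 100, 4)
            m = compute_metrics(ContingencyTable(*counts))
            assert m.balacc == pytest.approx((m.sen + m.spec) / 2)
            for v in m.as_dict().values():
                assert 0.0 <= v <= 1.0

    def test_matches_per_case_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 500))
            truth_v = rng.integers(0, 2, n)
            pred_v = rng.integers(0, 2, n)
            if truth_v.sum() in (0, n):
                truth_v[0], truth_v[-1] = 0, 1
            truth = {f"c{i}": int(truth_v[i]) for i in range(n)}
            pred = {f"c{i}": int(pred_v[i]) for i in range(n)}
            m = compute_metrics(build_contingency(truth, pred))
            # independent loop-based oracle
            tp = sum(1 for i in range(n) if truth_v[i] and pred_v[i])
            fn = sum(1 for i in range(n) if truth_v[i] and not pred_v[i])
            fp = sum(1 for i in range(n) if not truth_v[i] and pred_v[i])
            tn = n - tp - fn - fp
            assert m.sen == pytest.approx(tp / (tp + fn))
            assert m.spec == pytest.approx(tn / (tn + fp) if tn + fp else 1)
            assert m.acc == pytest.approx((tp + tn) / n)

    def test_swapping_roles_maps_sen_to_ppv(self, rng):
        truth, pred = verdicts_from_counts(12, 5, 7, 40)
        m_swapped = compute_metrics(build_contingency(pred, truth))
        m = compute_metrics(build_contingency(truth, pred))
        assert m_swapped.sen == pytest.approx(m.ppv)


class TestMeanOfComparisons:
    def setup_method(self):
        self.tables = [ContingencyTable(29, 2, 8, 216), ContingencyTable(28, 5, 9, 213)]
        self.metrics = [compute_metrics(t) for t in self.tables]

    def test_mean_counts(self):
        s = mean_of_comparisons(self.metrics, self.tables)
        assert s.mean_counts == {"tp": 28.5, "fn": 3.5, "fp": 8.5, "tn": 214.5}

    def test_mean_spec_and_balacc(self):
        s = mean_of_comparisons(self.metrics, self.tables)
        assert round_half_up(s.mean_metrics["spec"]) == 0.96
        assert round_half_up(s.mean_metrics["balacc"]) == 0.93

    def test_identical_sets_average_to_themselves(self):
        s = mean_of_comparisons([self.metrics[0]] * 2, [self.tables[0]] * 2)
        assert s.mean_metrics == self.metrics[0].as_dict()

    def test_empty_raises(self):
        with pytest.raises(ICHScreenError):
            mean_of_comparisons([], [])


class TestAdjudicate:
    def records(self, verdicts, rater, revised=None):
        revised = revised or {}
        return [
            RatingRecord(case_id=c, rater_id=rater, initial=v, revised=revised.get(c))
            for c, v in verdicts.items()
        ]

    def test_full_agreement_no_discrepancies(self):
        v = {"a": 1, "b": 0, "c": 1}
        res = adjudicate(self.records(v, "r1"), self.records(v, "r2"))
        assert res.discrepancies == [] and res.excluded == []
        assert res.finals == {c: (x, x) for c, x in v.items()}

    def test_revision_resolves_discrepancy(self):
        r1 = self.records({"a": 1, "b": 0}, "r1")
        r2 = self.records({"a": 0, "b": 0}, "r2", revised={"a": 1})
        res = adjudicate(r1, r2)
        assert res.discrepancies == ["a"]
        assert res.finals["a"] == (1, 1)

    def test_skipped_case_excluded(self):
        r1 = self.records({"a": 1, "b": 0}, "r1")
        r2 = [
            RatingRecord(case_id="a", rater_id="r2", initial=1),
            RatingRecord(case_id="b", rater_id="r2", initial=None),  # skipped
        ]
        res = adjudicate(r1, r2)
        assert res.excluded == ["b"]
        assert set(res.finals) == {"a"}

    def test_duplicate_case_raises(self):
        r1 = self.records({"a": 1}, "r1") * 2
        with pytest.raises(ICHScreenError):
            adjudicate(r1, self.records({"a": 1}, "r2"))


class TestRatingsCSV:
    def test_round_trip(self, tmp_path, rng):
        records = [
            RatingRecord(
                case_id=f"c{i}",
                rater_id="r1",
                initial=int(rng.integers(0, 2)),
                revised=int(rng.integers(0, 2)) if rng.random() < 0.2 else None,
            )
            for i in range(255)
        ]
        path = write_ratings_csv(records, tmp_path / "r.csv")
        assert read_ratings_csv(path) == records

    def test_conflicting_final_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("case_id,rater_id,initial,revised,final\nc1,r1,0,1,0\n")
        with pytest.raises(RatingsParseError) as err:
            read_ratings_csv(p)
        assert err.value.line == 2

    def test_header_only_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("case_id,rater_id,initial,revised,final\n")
        assert read_ratings_csv(p) == []
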