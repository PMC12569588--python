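import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppibias.data_model import Interaction
from ppibias.metrics import (
    ConfusionMatrix,
    PredictionRecord,
    PredictionSet,
    balanced_accuracy,
    f1,
    mcc,
    paired_metric_test,
    per_protein_matrices,
    pp_mcc,
    pp_metric,
    youden,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle (kept deliberately naive)
# ---------------------------------------------------------------------------

def _oracle_mcc(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def oracle_pp_mcc(records):
    """records: list of (a, b, actual, predicted). Re-derives every protein's
    submatrix by scanning all records; independent of the package."""
    proteins = sorted({p for r in records for p in {r[0], r[1]}})
    num = den = 0.0
    any_scored = False
    for prot in proteins:
        sub = [r for r in records if prot in (r[0], r[1])]
        tp = sum(1 for r in sub if r[2] == 1 and r[3] == 1)
        fn = sum(1 for r in sub if r[2] == 1 and r[3] == 0)
        fp = sum(1 for r in sub if r[2] == 0 and r[3] == 1)
        tn = sum(1 for r in sub if r[2] == 0 and r[3] == 0)
        if tp + fn == 0 or tn + fp == 0:
            continue  # skip rule: no actual positives or no actual negatives
        any_scored = True
        w = len(sub)
        num += w * _oracle_mcc(tp, tn, fp, fn)
        den += w
    if not any_scored:
        raise ValueError("all proteins skipped")
    return num / den


def _preds_from_tuples(tuples):
    return PredictionSet(
        [PredictionRecord(Interaction(a, b, act), pred) for a, b, act, pred in tuples]
    )


# ---------------------------------------------------------------------------
# raw MCC
# ---------------------------------------------------------------------------

class TestMCC:
    def test_perfect_and_antiperfect(self):
        assert mcc(ConfusionMatrix(tp=5, tn=5)) == 1.0
        assert mcc(ConfusionMatrix(fp=5, fn=5)) == -1.0

    def test_derived_value(self):
        # (1*1 - 1*0) / sqrt(2*1*2*1) = 0.5
        assert mcc(ConfusionMatrix(tp=1, tn=1, fp=1, fn=0)) == pytest.approx(0.5)

    def test_zero_marginal_convention(self):
        assert mcc(ConfusionMatrix(tp=3, fn=1)) == 0.0

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            mcc(ConfusionMatrix())

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_bounds_and_oracle(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        value = mcc(ConfusionMatrix(tp, tn, fp, fn))
        assert -1.0 <= value <= 1.0
        assert value == pytest.approx(_oracle_mcc(tp, tn, fp, fn), abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1)


class TestBaseMetrics:
    def test_f1_balanced_accuracy_youden(self):
        cm = ConfusionMatrix(tp=3, tn=2, fp=1, fn=1)
        assert f1(cm) == pytest.approx(6 / 8)
        assert balanced_accuracy(cm) == pytest.approx((3 / 4 + 2 / 3) / 2)
        assert youden(cm) == pytest.approx(3 / 4 + 2 / 3 - 1)


# ---------------------------------------------------------------------------
# per-protein machinery
# ---------------------------------------------------------------------------

class TestPerProteinMatrices:
    def test_single_record_credits_both_endpoints(self):
        preds = _preds_from_tuples([("A", "B", 1, 1)])
        mats = per_protein_matrices(preds)
        assert mats["A"] == ConfusionMatrix(tp=1)
        assert mats["B"] == ConfusionMatrix(tp=1)

    def test_self_interaction_credited_once(self):
        preds = _preds_from_tuples([("A", "A", 1, 0)])
        mats = per_protein_matrices(preds)
        assert mats["A"] == ConfusionMatrix(fn=1)

    def test_toy6_hand_enumeration(self, toy6_predictions):
        mats = per_protein_matrices(toy6_predictions)
        assert mats["A"] == ConfusionMatrix(tp=1, tn=1, fp=1, fn=0)
        assert mats["B"] == ConfusionMatrix(tp=2, fn=1)
        assert mats["C"] == ConfusionMatrix(tn=1, fp=1, fn=1)
        assert mats["D"] == ConfusionMatrix(tp=1, tn=2)

    def test_pooling_invariance_under_fold_shuffling(self, toy6_predictions):
        retagged = PredictionSet(
            [
                PredictionRecord(r.interaction, r.predicted, fold_id=i % 3)
                for i, r in enumerate(toy6_predictions)
            ]
        )
        assert per_protein_matrices(retagged) == per_protein_matrices(toy6_predictions)

    def test_first_credit_mode(self):
        preds = _preds_from_tuples([("A", "B", 1, 1), ("B", "A", 0, 0)])
        mats = per_protein_matrices(preds, credit="first")
        assert mats["A"] == ConfusionMatrix(tp=1)
        assert mats["B"] == ConfusionMatrix(tn=1)


class TestPpMcc:
    def test_worked_example(self, toy6_predictions):
        value, breakdown = pp_mcc(toy6_predictions)
        assert value == pytest.approx(1 / 3, abs=1e-12)
        by = {s.protein: s for s in breakdown.scores}
        assert by["B"].skipped and by["B"].value is None
        assert by["A"].value == pytest.approx(0.5)
        assert by["C"].value == pytest.approx(-0.5)
        assert by["D"].value == pytest.approx(1.0)
        assert [by[p].weight for p in "ABCD"] == [3, 3, 3, 3]
        assert breakdown.n_skipped == 1
        assert breakdown.total_weight == 9

    def test_perfect_predictions(self):
        preds = _preds_from_tuples(
            [("A", "B", 1, 1), ("A", "B2", 0, 0), ("B", "A2", 0, 0), ("B2", "B", 1, 1)]
        )
        value, _ = pp_mcc(preds)
        assert value == pytest.approx(1.0)

    def test_prediction_flip_antisymmetry(self, toy6_predictions):
        value, breakdown = pp_mcc(toy6_predictions)
        flipped_value, flipped_breakdown = pp_mcc(toy6_predictions.flipped())
        assert flipped_value == pytest.approx(-value, abs=1e-12)
        assert {s.protein for s in breakdown.scores if s.skipped} == {
            s.protein for s in flipped_breakdown.scores if s.skipped
        }

    def test_duplication_invariance(self, toy6_predictions):
        doubled = PredictionSet(toy6_predictions.records * 2)
        assert doubled.mcc() == pytest.approx(toy6_predictions.mcc(), abs=1e-12)
        assert pp_mcc(doubled)[0] == pytest.approx(pp_mcc(toy6_predictions)[0], abs=1e-12)

    def test_all_skipped_error(self):
        preds = _preds_from_tuples([("A", "B", 1, 1), ("A", "C", 1, 0)])
        with pytest.raises(ValueError, match="skipped"):
            pp_mcc(preds)

    def test_zero_predicted_marginal_is_scored_not_skipped(self):
        # both actual classes present but the predictor is constant:
        # MCC_i = 0 via the zero-marginal convention, protein not skipped
        preds = _preds_from_tuples([("A", "B", 1, 1), ("A", "C", 0, 1)])
        value, breakdown = pp_mcc(preds)
        by = {s.protein: s for s in breakdown.scores}
        assert not by["A"].skipped
        assert by["A"].value == 0.0

    def test_weight_conservation(self, toy6_predictions):
        _, breakdown = pp_mcc(toy6_predictions)
        n_self = sum(1 for r in toy6_predictions if r.interaction.is_self)
        n_other = len(toy6_predictions) - n_self
        assert sum(s.weight for s in breakdown.scores) == 2 * n_other + n_self

    def test_constant_per_protein_predictor_scores_zero(self):
        # per-first-protein constant predictions + first-credit submatrices:
        # every scored protein contributes 0 (or is skipped)
        preds = _preds_from_tuples(
            [("A", "B", 1, 1), ("A", "C", 0, 1), ("A", "D", 0, 1),
             ("B", "C", 1, 0), ("B", "D", 0, 0)]
        )
        value, breakdown = pp_metric(preds, credit="first")
        assert value == 0.0
        for s in breakdown.scores:
            assert s.skipped or s.value == 0.0

    def test_pp_metric_other_base(self, toy6_predictions):
        value, _ = pp_metric(toy6_predictions, balanced_accuracy)
        # A: (1/1 + 1/2)/2 = 0.75 ; C: (0/1 + 1/2)/2 = 0.25 ; D: 1.0
        assert value == pytest.approx((3 * 0.75 + 3 * 0.25 + 3 * 1.0) / 9)


# randomized oracle equivalence (the acceptance-scale sweep lives in
# tests/test_acceptance.py; this is a quick smoke version)
@settings(max_examples=200, deadline=None)
@given(st.data())
def test_pp_mcc_matches_bruteforce_oracle(data):
    n_proteins = data.draw(st.integers(2, 8))
    proteins = [f"P{i}" for i in range(n_proteins)]
    n_records = data.draw(st.integers(1, 20))
    tuples = [
        (
            data.draw(st.sampled_from(proteins)),
            data.draw(st.sampled_from(proteins)),
            data.draw(st.integers(0, 1)),
            data.draw(st.integers(0, 1)),
        )
        for _ in range(n_records)
    ]
    preds = _preds_from_tuples(tuples)
    try:
        expected = oracle_pp_mcc(tuples)
    except ValueError:
        with pytest.raises(ValueError):
            pp_mcc(preds)
        return
    value, _ = pp_mcc(preds)
    assert value == pytest.approx(expected, abs=1e-12)
    assert -1.0 <= value <= 1.0


# ---------------------------------------------------------------------------
# paired test
# ---------------------------------------------------------------------------

class TestPairedMetricTest:
    def test_textbook_formula(self):
        diffs = [0.1, 0.2, 0.15, 0.05]
        a = [0.5, 0.6, 0.55, 0.45]
        b = [x - d for x, d in zip(a, diffs)]
        res = paired_metric_test(a, b)
        n = len(diffs)
        mean = sum(diffs) / n
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
        t = mean / (sd / math.sqrt(n))
        assert res.statistic == pytest.approx(t, rel=1e-10)
        from scipy import stats

        assert res.pvalue == pytest.approx(2 * stats.t.sf(abs(t), n - 1), rel=1e-10)
        assert res.degenerate is None

    def test_identical_differences_degenerate(self):
        a = [0.5, 0.6, 0.7, 0.4, 0.3]
        b = [x - 0.1 for x in a]
        res = paired_metric_test(a, b)
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.degenerate == "all differences identical"

    def test_identical_vectors_error(self):
        with pytest.raises(ValueError, match="identical"):
            paired_metric_test([0.1, 0.2], [0.1, 0.2])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_metric_test([0.1], [0.1, 0.2])
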