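"""Strict/lenient scoring, folds, micro vs macro, IAA, CV and ablation."""

import pytest
from hypothesis import given, settings, strategies as st

from resner import Mention
from resner import evaluation as ev
from resner.evaluation import (CVConfig, EvalResult, EvaluationError,
                               compare_mentions, cross_validate, iaa,
                               kfold_split, prf, summarize_folds)


def m(start, end, doc="d"):
    return Mention(doc, start, end, "x" * (end - start))


class TestPrf:
    def test_arithmetic(self):
        assert prf(3, 1, 1) == (75.0, 75.0, 75.0)

    def test_degenerate_zero(self):
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_perfect(self):
        assert prf(1, 0, 0) == (100.0, 100.0, 100.0)


class TestCompareMentions:
    def test_exact_match_strict(self):
        res = compare_mentions([m(5, 10)], [m(5, 10)], "strict")
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_partial_overlap_modes(self):
        gold, pred = [m(0, 13)], [m(0, 4)]
        strict = compare_mentions(gold, pred, "strict")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        lenient = compare_mentions(gold, pred, "lenient")
        assert (lenient.tp, lenient.fp, lenient.fn) == (1, 0, 0)

    def test_empty_predictions(self):
        res = compare_mentions([m(0, 2), m(3, 5), m(6, 8)], [], "strict")
        assert res.fn == 3 and res.recall == 0.0

    def test_one_to_one_pairing(self):
        # one long prediction cannot absorb two gold mentions
        gold = [m(0, 4), m(6, 10)]
        pred = [m(0, 10)]
        res = compare_mentions(gold, pred, "lenient")
        assert (res.tp, res.fp, res.fn) == (1, 0, 1)

    def test_overlapping_predictions_rejected(self):
        with pytest.raises(EvaluationError):
            compare_mentions([m(0, 2)], [m(0, 4), m(3, 6)], "strict")

    def test_documents_kept_apart(self):
        res = compare_mentions([m(0, 4, "a")], [m(0, 4, "b")], "strict")
        assert res.tp == 0

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_lenient_dominates_strict(self, data):
        """Any strict match is a lenient match, so every lenient score
        bounds its strict counterpart from above."""
        def spans(n):
            starts = data.draw(st.lists(st.integers(0, 60), min_size=0,
                                        max_size=n, unique=True))
            return [m(3 * s, 3 * s + data.draw(st.integers(1, 3)))
                    for s in sorted(starts)]
        gold, pred = spans(8), spans(8)
        strict = compare_mentions(gold, pred, "strict")
        lenient = compare_mentions(gold, pred, "lenient")
        assert lenient.tp >= strict.tp
        assert lenient.precision >= strict.precision
        assert lenient.recall >= strict.recall
        assert lenient.f_score >= strict.f_score

    @settings(derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_tp_symmetric_under_swap(self, data):
        starts_a = data.draw(st.lists(st.integers(0, 40), unique=True))
        starts_b = data.draw(st.lists(st.integers(0, 40), unique=True))
        a = [m(3 * s, 3 * s + 2) for s in sorted(starts_a)]
        b = [m(3 * s, 3 * s + 2) for s in sorted(starts_b)]
        for mode in ("strict", "lenient"):
            ab = compare_mentions(a, b, mode)
            ba = compare_mentions(b, a, mode)
            assert ab.tp == ba.tp
            assert (ab.fp, ab.fn) == (ba.fn, ba.fp)


class TestIaa:
    def test_identical_sets_perfect(self):
        anns = {"d": [m(0, 4), m(6, 10)]}
        for mode in ("strict", "lenient"):
            res = iaa(anns, anns, mode)
            assert res["a_as_gold"].f_score == 100.0
            assert res["b_as_gold"].f_score == 100.0

    def test_widened_spans_split_modes(self):
        a = {"d": [m(3, 6), m(9, 12)]}
        b = {"d": [m(2, 7), m(8, 13)]}
        assert iaa(a, b, "strict")["a_as_gold"].f_score == 0.0
        assert iaa(a, b, "lenient")["a_as_gold"].f_score == 100.0

    def test_empty_annotator(self):
        res = iaa({"d": [m(0, 3)]}, {"d": []}, "strict")
        assert res["a_as_gold"].f_score == 0.0

    def test_disjoint_documents_rejected(self):
        with pytest.raises(EvaluationError):
            iaa({"a": []}, {"b": []}, "strict")


class TestKfold:
    def test_even_partition(self):
        spec = kfold_split([f"d{i}" for i in range(10)], 5, seed=1)
        sizes = [len(spec.fold_docs(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_seed_reproducible(self):
        ids = [f"d{i}" for i in range(12)]
        assert kfold_split(ids, 4, 9).assignment == kfold_split(ids, 4, 9).assignment

    def test_uneven_sizes_balanced(self):
        spec = kfold_split([f"d{i}" for i in range(11)], 5, seed=0)
        sizes = sorted(len(spec.fold_docs(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_too_many_folds_rejected(self):
        with pytest.raises(EvaluationError):
            kfold_split(["a", "b"], 3, 0)


class TestSummaries:
    def test_micro_vs_macro_on_unbalanced_folds(self):
        folds = [EvalResult(1, 0, 1, "strict"), EvalResult(3, 0, 1, "strict")]
        s = summarize_folds(folds)
        assert s["mean"]["recall"] == 62.5          # (50 + 75) / 2
        assert s["micro"]["recall"] == round(100 * 4 / 6, 1)  # pooled 4/6

    def test_micro_equals_macro_on_balanced_folds(self):
        folds = [EvalResult(2, 1, 2, "strict"), EvalResult(2, 1, 2, "strict")]
        s = summarize_folds(folds)
        assert s["mean"] == s["micro"]

    def test_min_max_rows(self):
        folds = [EvalResult(1, 1, 3, "strict"), EvalResult(3, 0, 1, "strict")]
        s = summarize_folds(folds)
        assert s["min"]["recall"] == 25.0 and s["max"]["recall"] == 75.0


@pytest.fixture(scope="module")
def cv_report(toy_dict, small_corpus):
    return cross_validate(small_corpus, toy_dict, CVConfig(epochs=2),
                          k=3, seed=4)


class TestCrossValidation:
    def test_reports_all_systems_and_modes(self, cv_report):
        assert set(cv_report["systems"]) == {"dictionary", "tagger",
                                             "tagger+postprocess"}
        for by_mode in cv_report["systems"].values():
            assert set(by_mode) == {"strict", "lenient"}
            assert len(by_mode["strict"]["folds"]) == 3

    def test_lenient_at_least_strict(self, cv_report):
        for by_mode in cv_report["systems"].values():
            assert by_mode["lenient"]["micro"]["f_score"] >= \
                by_mode["strict"]["micro"]["f_score"]

    def test_seeded_rerun_identical(self, toy_dict, small_corpus, cv_report):
        rerun = cross_validate(small_corpus, toy_dict, CVConfig(epochs=2),
                               k=3, seed=4)
        assert rerun == cv_report

    def test_report_serialisation(self, cv_report):
        tsv = ev.report_to_tsv(cv_report)
        assert "micro" in tsv and tsv.count("fold1") == 6  # 3 systems x 2 modes
        assert ev.report_to_json(cv_report)


class TestAblation:
    def test_unknown_group_rejected(self, toy_dict, small_corpus):
        with pytest.raises(EvaluationError):
            ev.ablation(small_corpus, toy_dict, ["phonetic"], k=2, seed=0)

    def test_rows_match_requested_configurations(self, small_corpus, toy_dict):
        rep = ev.ablation(small_corpus, toy_dict, ["syntactic"],
                          CVConfig(epochs=2), k=2, seed=3)
        assert set(rep["rows"]) == {"all", "no_syntactic"}

    def test_empty_drop_equals_baseline(self, small_corpus, toy_dict):
        rep = ev.ablation(small_corpus, toy_dict, [], CVConfig(epochs=2),
                          k=2, seed=3)
        cfg = CVConfig(epochs=2, postprocess=False,
                       run_dictionary_baseline=False)
        base = cross_validate(small_corpus, toy_dict, cfg, k=2, seed=3)
        assert rep["rows"]["all"] == base["systems"]["tagger"]
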