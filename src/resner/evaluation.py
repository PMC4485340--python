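"""Mention-level evaluation: strict/lenient scoring, cross-validation,
feature ablation and inter-annotator agreement.

Strict matching credits a prediction only when its character offsets
exactly equal a gold mention's; lenient matching credits any character
overlap, paired greedily one-to-one in gold order (so one long prediction
cannot absorb several gold mentions).  Scores are percentages;
zero-denominator cases score 0 by convention.

Cross-validation is document-level: a seeded shuffle followed by
round-robin assignment, so no document appears in two folds and fold sizes
differ by at most one.  Summaries report per-fold min/max/mean plus the
micro-average computed from pooled TP/FP/FN — the two differ exactly when
folds are unbalanced.
"""

from __future__ import annotations

import csv
import io
import json
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus import Document, Mention, bio_to_mentions, mentions_to_bio
from .dictionary import MatchPolicy, ResourceDictionary, match
from .features import DEFAULT_WINDOW, FEATURE_GROUPS
from . import postprocess as pp
from . import tagger as tg

MODES = ("strict", "lenient")


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F-score as percentages (0 on empty denominators)."""
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    mode: str = "strict"

    @property
    def precision(self) -> float:
        return prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return prf(self.tp, self.fp, self.fn)[1]

    @property
    def f_score(self) -> float:
        return prf(self.tp, self.fp, self.fn)[2]

    def __add__(self, other: "EvalResult") -> "EvalResult":
        if self.mode != other.mode:
            raise EvaluationError("cannot pool results across modes")
        return EvalResult(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.mode)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "mode": self.mode,
                "precision": round(self.precision, 1),
                "recall": round(self.recall, 1),
                "f_score": round(self.f_score, 1)}


# ---------------------------------------------------------------------------
# Mention comparison
# ---------------------------------------------------------------------------

def _check_nonoverlap(mentions: Sequence[Mention], kind: str) -> None:
    ms = sorted(mentions, key=lambda m: (m.doc_id, m.start))
    for a, b in zip(ms, ms[1:]):
        if a.doc_id == b.doc_id and a.overlaps(b):
            raise EvaluationError(
                f"overlapping {kind} mentions in {a.doc_id} at {a.start}/{b.start}")


def compare_mentions(gold: Sequence[Mention], pred: Sequence[Mention],
                     mode: str = "strict", typed: bool = False) -> EvalResult:
    """Score predictions against gold under strict or lenient matching.

    Matching is one-to-one: each gold and each predicted mention is used at
    most once.  Lenient pairing is greedy in gold order, preferring the
    overlapping prediction with the largest overlap (ties to the earlier
    prediction).  Typed evaluation additionally requires equal rtype; the
    default is untyped spans.
    """
    if mode not in MODES:
        raise EvaluationError(f"unknown mode {mode!r}")
    _check_nonoverlap(gold, "gold")
    _check_nonoverlap(pred, "predicted")
    used = [False] * len(pred)
    tp = 0
    for g in sorted(gold, key=lambda m: (m.doc_id, m.start)):
        best, best_ov = None, 0
        for k, p in enumerate(pred):
            if used[k] or p.doc_id != g.doc_id:
                continue
            if typed and p.rtype != g.rtype:
                continue
            if mode == "strict":
                if (p.start, p.end) == (g.start, g.end):
                    best = k
                    break
            else:
                ov = min(g.end, p.end) - max(g.start, p.start)
                if ov > 0 and ov > best_ov:
                    best, best_ov = k, ov
        if best is not None:
            used[best] = True
            tp += 1
    fp = used.count(False)
    fn = len(gold) - tp
    return EvalResult(tp=tp, fp=fp, fn=fn, mode=mode)


def iaa(annotations_a: Mapping[str, Sequence[Mention]],
        annotations_b: Mapping[str, Sequence[Mention]],
        mode: str = "strict") -> dict[str, EvalResult]:
    """Inter-annotator agreement over a shared document set.

    The measure is asymmetric (one annotator plays gold), so both
    directions are returned: ``a_as_gold`` scores B against A and
    ``b_as_gold`` the converse.
    """
    docs = set(annotations_a) & set(annotations_b)
    if not docs:
        raise EvaluationError("annotators share no documents")
    a = [m for d in sorted(docs) for m in annotations_a[d]]
    b = [m for d in sorted(docs) for m in annotations_b[d]]
    return {"a_as_gold": compare_mentions(a, b, mode),
            "b_as_gold": compare_mentions(b, a, mode)}


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSpec:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_docs(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)


def kfold_split(doc_ids: Sequence[str], k: int, seed: int = 0) -> FoldSpec:
    """Document-level folds: seeded shuffle, then round-robin assignment.
    Fold sizes differ by at most one."""
    ids = list(doc_ids)
    if k > len(ids):
        raise EvaluationError(f"k={k} exceeds {len(ids)} documents")
    if k < 2:
        raise EvaluationError("k must be at least 2")
    rng = random.Random(seed)
    rng.shuffle(ids)
    return FoldSpec(k=k, assignment={d: i % k for i, d in enumerate(ids)},
                    seed=seed)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_folds(fold_results: Sequence[EvalResult]) -> dict:
    """Min/max/mean of per-fold P/R/F plus the micro-average from pooled
    counts, mirroring the usual cross-validation report layout."""
    if not fold_results:
        raise EvaluationError("no fold results to summarise")
    per = [(r.precision, r.recall, r.f_score) for r in fold_results]
    pooled = fold_results[0]
    for r in fold_results[1:]:
        pooled = pooled + r
    def agg(fn):
        return {"precision": round(fn([p for p, _, _ in per]), 1),
                "recall": round(fn([r for _, r, _ in per]), 1),
                "f_score": round(fn([f for _, _, f in per]), 1)}
    mean = lambda xs: sum(xs) / len(xs)
    return {"folds": [r.as_dict() for r in fold_results],
            "min": agg(min), "max": agg(max), "mean": agg(mean),
            "micro": {"precision": round(pooled.precision, 1),
                      "recall": round(pooled.recall, 1),
                      "f_score": round(pooled.f_score, 1)},
            "pooled_counts": {"tp": pooled.tp, "fp": pooled.fp, "fn": pooled.fn}}


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Configuration shared by cross-validation and ablation runs."""

    groups: tuple[str, ...] = FEATURE_GROUPS
    window: tuple[int, ...] = DEFAULT_WINDOW
    epochs: int = 8
    postprocess: bool = True
    blacklist: tuple[str, ...] = pp.DEFAULT_BLACKLIST
    match_policy: MatchPolicy = field(default_factory=MatchPolicy)
    run_dictionary_baseline: bool = True


def cross_validate(corpus: Sequence[tuple[Document, Sequence[Mention]]],
                   d: ResourceDictionary | None,
                   config: CVConfig | None = None,
                   k: int = 5, seed: int = 0) -> dict:
    """Document-level k-fold cross-validation of the sequence tagger and,
    optionally, of the dictionary baseline.

    Per fold: the tagger is trained on the k−1 training folds, tags the
    held-out fold, and (when enabled) the transductive two-pass
    post-processing is applied over that held-out fold.  The dictionary
    baseline needs no training and is evaluated on the same held-out fold.
    Both strict and lenient scores are reported; folds with zero gold
    mentions are still scored and flagged.
    """
    config = config or CVConfig()
    by_id = {doc.doc_id: (doc, list(mentions)) for doc, mentions in corpus}
    spec = kfold_split(sorted(by_id), k=k, seed=seed)
    systems: dict[str, dict[str, list[EvalResult]]] = {}
    flagged: list[str] = []

    def add(system: str, mode: str, res: EvalResult) -> None:
        systems.setdefault(system, {m: [] for m in MODES})[mode].append(res)

    for fold in range(k):
        test_ids = spec.fold_docs(fold)
        train_ids = [i for i in sorted(by_id) if i not in set(test_ids)]
        test = [by_id[i] for i in test_ids]
        gold = [m for _, ms in test for m in ms]
        if not gold:
            flagged.append(f"fold {fold} has zero gold mentions")

        if config.run_dictionary_baseline and d is not None:
            pred = [m for doc, _ in test
                    for m in match(doc, d, config.match_policy)]
            for mode in MODES:
                add("dictionary", mode, compare_mentions(gold, pred, mode))

        train_pairs = [(doc, mentions_to_bio(doc, ms))
                       for doc, ms in (by_id[i] for i in train_ids)]
        model = tg.train(train_pairs, d, groups=config.groups,
                         window=config.window, epochs=config.epochs, seed=seed)
        tagged = [(doc, tg.tag(model, doc, d)) for doc, _ in test]
        pred = [m for doc, seq in tagged for m in bio_to_mentions(doc, seq)]
        for mode in MODES:
            add("tagger", mode, compare_mentions(gold, pred, mode))
        if config.postprocess:
            relabelled = pp.apply(tagged, d, blacklist=config.blacklist)
            pred_pp = [m for doc, seq in relabelled
                       for m in bio_to_mentions(doc, seq, source="postprocess")]
            for mode in MODES:
                add("tagger+postprocess", mode,
                    compare_mentions(gold, pred_pp, mode))

    report = {"k": k, "seed": seed, "flags": flagged,
              "fold_assignment": spec.assignment, "systems": {}}
    for system, by_mode in systems.items():
        report["systems"][system] = {mode: summarize_folds(results)
                                     for mode, results in by_mode.items()}
    return report


# ---------------------------------------------------------------------------
# Feature ablation
# ---------------------------------------------------------------------------

def ablation(corpus: Sequence[tuple[Document, Sequence[Mention]]],
             d: ResourceDictionary | None,
             groups_to_drop: Sequence[str] = FEATURE_GROUPS,
             config: CVConfig | None = None,
             k: int = 5, seed: int = 0) -> dict:
    """Drop one feature group at a time and re-run cross-validation.

    Post-processing is disabled throughout so feature contributions are not
    masked by the second pass (which leans on the dictionary), and the fold
    assignment and seed are shared across configurations.  The baseline row
    ("all") uses every feature group.
    """
    base = config or CVConfig()
    unknown = set(groups_to_drop) - set(FEATURE_GROUPS)
    if unknown:
        raise EvaluationError(f"unknown feature group(s) {sorted(unknown)}")
    rows: dict[str, dict] = {}
    configs: dict[str, tuple[str, ...]] = {"all": tuple(FEATURE_GROUPS)}
    for g in groups_to_drop:
        configs[f"no_{g}"] = tuple(x for x in FEATURE_GROUPS if x != g)
    for name, groups in configs.items():
        cfg = CVConfig(groups=groups, window=base.window, epochs=base.epochs,
                       postprocess=False, blacklist=base.blacklist,
                       match_policy=base.match_policy,
                       run_dictionary_baseline=False)
        rep = cross_validate(corpus, d, cfg, k=k, seed=seed)
        rows[name] = rep["systems"]["tagger"]
    return {"k": k, "seed": seed, "rows": rows}


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_tsv(report: Mapping) -> str:
    """Flatten a cross-validation report into per-fold and summary rows."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["system", "mode", "row", "precision", "recall", "f_score",
                "tp", "fp", "fn"])
    for system, by_mode in report.get("systems", {}).items():
        for mode, summ in by_mode.items():
            for i, fold in enumerate(summ["folds"], 1):
                w.writerow([system, mode, f"fold{i}", fold["precision"],
                            fold["recall"], fold["f_score"],
                            fold["tp"], fold["fp"], fold["fn"]])
            for row in ("min", "max", "mean", "micro"):
                s = summ[row]
                w.writerow([system, mode, row, s["precision"], s["recall"],
                            s["f_score"], "", "", ""])
    return buf.getvalue()
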