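"""Linear-chain sequence tagger for B-I-O resource-name labelling.

The learner is an averaged structured perceptron with first-order
transition features and Viterbi decoding — a deterministic linear-chain
model trained on the feature vectors from :mod:`resner.features`.  The
module's surface is learner-agnostic: ``train`` / ``tag`` / ``save`` /
``load`` plus label-sequence repair, so a different linear-chain backend
can be swapped in behind the same contract.

All randomness (epoch shuffling) flows from a single integer seed recorded
in the model artifact; training twice with the same corpus, configuration
and seed yields byte-identical tag output.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, LabelSequence
from .dictionary import ResourceDictionary
from .features import DEFAULT_WINDOW, FEATURE_GROUPS, featurize_document

LABELS = ("O", "B", "I")
_INIT = "<s>"  # virtual previous label at sentence start


class TaggerError(ValueError):
    pass


@dataclass
class TaggerModel:
    """Learned weights plus the configuration needed to reproduce them.

    ``weights`` maps "feature=value" strings to per-label score vectors;
    ``transitions`` maps a previous label to per-label score vectors.
    """

    weights: dict[str, list[float]] = field(default_factory=dict)
    transitions: dict[str, list[float]] = field(default_factory=dict)
    groups: tuple[str, ...] = FEATURE_GROUPS
    window: tuple[int, ...] = DEFAULT_WINDOW
    epochs: int = 8
    seed: int = 0

    # -- persistence -------------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        """Write the model artifact: weights file plus a JSON sidecar with
        the training configuration and seed."""
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        with open(model_dir / "weights.json", "w", encoding="utf-8") as fh:
            json.dump({"weights": self.weights, "transitions": self.transitions},
                      fh)
        with open(model_dir / "config.json", "w", encoding="utf-8") as fh:
            json.dump({"groups": list(self.groups), "window": list(self.window),
                       "epochs": self.epochs, "seed": self.seed,
                       "labels": list(LABELS),
                       "backend": "averaged-structured-perceptron"},
                      fh, indent=2)

    @classmethod
    def load(cls, model_dir: str | Path) -> "TaggerModel":
        model_dir = Path(model_dir)
        cfg = json.loads((model_dir / "config.json").read_text(encoding="utf-8"))
        blob = json.loads((model_dir / "weights.json").read_text(encoding="utf-8"))
        return cls(weights=blob["weights"], transitions=blob["transitions"],
                   groups=tuple(cfg["groups"]), window=tuple(cfg["window"]),
                   epochs=cfg["epochs"], seed=cfg["seed"])


def _vec_to_keys(vec: dict[str, str]) -> list[str]:
    return [f"{k}={v}" for k, v in vec.items()]


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _viterbi(sent_keys: list[list[str]], weights: dict[str, list[float]],
             transitions: dict[str, list[float]]) -> list[str]:
    n = len(sent_keys)
    if n == 0:
        return []
    L = len(LABELS)
    zeros = [0.0] * L
    emit = []
    for keys in sent_keys:
        e = [0.0] * L
        for k in keys:
            w = weights.get(k)
            if w:
                for li in range(L):
                    e[li] += w[li]
        emit.append(e)
    init_t = transitions.get(_INIT, zeros)
    score = [emit[0][li] + init_t[li] for li in range(L)]
    back: list[list[int]] = []
    for t in range(1, n):
        trans = [transitions.get(lab, zeros) for lab in LABELS]
        new = [0.0] * L
        bp = [0] * L
        for li in range(L):
            best, arg = None, 0
            for pj in range(L):
                s = score[pj] + trans[pj][li]
                if best is None or s > best:
                    best, arg = s, pj
            new[li] = best + emit[t][li]
            bp[li] = arg
        score = new
        back.append(bp)
    li = max(range(L), key=lambda i: (score[i], -i))
    path = [li]
    for bp in reversed(back):
        li = bp[li]
        path.append(li)
    return [LABELS[i] for i in reversed(path)]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(corpus: Sequence[tuple[Document, LabelSequence]],
          d: ResourceDictionary | None = None,
          groups: Sequence[str] = FEATURE_GROUPS,
          window: Sequence[int] = DEFAULT_WINDOW,
          epochs: int = 8, seed: int = 0) -> TaggerModel:
    """Train the sequence labeller on featureised B-I-O documents.

    Raises :class:`TaggerError` on an empty corpus or one with no positive
    (B/I) labels — there is nothing learnable in either case.
    """
    if not corpus:
        raise TaggerError("empty training corpus: nothing to learn from")
    sents: list[tuple[list[list[str]], list[str]]] = []
    n_positive = 0
    for doc, seq in corpus:
        if len(seq.labels) != len(doc.tokens):
            raise TaggerError(f"{doc.doc_id}: label/token length mismatch")
        feats = featurize_document(doc, d, groups=groups, window=window)
        for si, (a, b) in enumerate(doc.sentences):
            keys = [_vec_to_keys(v) for v in feats[si]]
            labels = seq.labels[a:b]
            n_positive += sum(1 for l in labels if l != "O")
            sents.append((keys, labels))
    if n_positive == 0:
        raise TaggerError(
            "training corpus contains no B/I labels: an all-O corpus is not learnable")

    lab_i = {l: i for i, l in enumerate(LABELS)}
    L = len(LABELS)
    weights: dict[str, list[float]] = {}
    trans: dict[str, list[float]] = {}
    # averaging accumulators (lazy update via timestamps)
    w_tot: dict[str, list[float]] = {}
    w_ts: dict[str, int] = {}
    t_tot: dict[str, list[float]] = {}
    t_ts: dict[str, int] = {}
    step = 0

    rng = random.Random(seed)
    order = list(range(len(sents)))
    for _epoch in range(epochs):
        rng.shuffle(order)
        for idx in order:
            keys, gold = sents[idx]
            pred = _viterbi(keys, weights, trans)
            step += 1
            if pred == gold:
                continue
            prev_g, prev_p = _INIT, _INIT
            for t, (g, p) in enumerate(zip(gold, pred)):
                if g != p:
                    gi, pi = lab_i[g], lab_i[p]
                    for k in keys[t]:
                        _upd(weights, w_tot, w_ts, k, gi, +1.0, step, L)
                        _upd(weights, w_tot, w_ts, k, pi, -1.0, step, L)
                if (prev_g, g) != (prev_p, p):
                    _upd(trans, t_tot, t_ts, prev_g, lab_i[g], +1.0, step, L)
                    _upd(trans, t_tot, t_ts, prev_p, lab_i[p], -1.0, step, L)
                prev_g, prev_p = g, p

    final_w = _average(weights, w_tot, w_ts, step, L)
    final_t = _average(trans, t_tot, t_ts, step, L)
    return TaggerModel(weights=final_w, transitions=final_t,
                       groups=tuple(groups), window=tuple(window),
                       epochs=epochs, seed=seed)


def _upd(table, tot, ts, key, li, delta, step, L):
    if key not in table:
        table[key] = [0.0] * L
        tot[key] = [0.0] * L
        ts[key] = [0] * L
    tot[key][li] += (step - ts[key][li]) * table[key][li]
    ts[key][li] = step
    table[key][li] += delta


def _average(table, tot, ts, final_step, L):
    out = {}
    for key, w in table.items():
        avg = [0.0] * L
        for li in range(L):
            total = tot[key][li] + (final_step - ts[key][li]) * w[li]
            avg[li] = total / max(final_step, 1)
        if any(abs(v) > 1e-12 for v in avg):
            out[key] = avg
    return out


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def tag(model: TaggerModel, doc: Document,
        d: ResourceDictionary | None = None) -> LabelSequence:
    """Decode one label per token (Viterbi per sentence), then repair the
    sequence to valid B-I-O."""
    feats = featurize_document(doc, d, groups=model.groups, window=model.window)
    labels: list[str] = []
    for si in range(len(doc.sentences)):
        keys = [_vec_to_keys(v) for v in feats[si]]
        decoded = _viterbi(keys, model.weights, model.transitions)
        # repair per sentence: a mention never crosses a sentence boundary
        labels.extend(repair_bio(LabelSequence(doc.doc_id, decoded)).labels)
    return LabelSequence(doc_id=doc.doc_id, labels=labels)


def tag_corpus(model: TaggerModel, docs: Iterable[Document],
               d: ResourceDictionary | None = None
               ) -> list[tuple[Document, LabelSequence]]:
    return [(doc, tag(model, doc, d)) for doc in docs]


def repair_bio(seq: LabelSequence) -> LabelSequence:
    """Make a label sequence valid: every I not preceded by B or I becomes
    B.  Idempotent; the identity on already-valid sequences."""
    out: list[str] = []
    prev = "O"
    for lab in seq.labels:
        if lab == "I" and prev == "O":
            lab = "B"
        out.append(lab)
        prev = lab
    return LabelSequence(doc_id=seq.doc_id, labels=out)
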