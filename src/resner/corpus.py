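"""Document model and corpus I/O for resource-mention recognition.

A :class:`Document` holds full text plus character-offset tokens carrying
POS tag, lemma and sentence index.  Gold and predicted annotations are
:class:`Mention` spans (0-based, half-open character offsets).  This module
also converts between mentions and per-token B-I-O label sequences, and
reads/writes the standoff (brat-style ``.txt``/``.ann``), JSON-lines and
CoNLL interchange formats.

The tokeniser, sentence splitter and POS tagger are rule-based providers:
any annotator producing tokens that satisfy the :class:`Token` invariants
(non-overlapping, sorted, exact slices of the text) is interchangeable
with them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("resner")

# Mention types: databases, software/tools, or undetermined.
DATABASE = "DATABASE"
SOFTWARE = "SOFTWARE"
UNSPECIFIED = "UNSPECIFIED"

RTYPES = (DATABASE, SOFTWARE, UNSPECIFIED)


class CorpusError(ValueError):
    """Raised for malformed documents, annotations or label sequences."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    """A token anchored to the document text by character offsets."""

    text: str
    start: int
    end: int
    pos: str = ""
    lemma: str = ""
    sent_index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"bad token offsets ({self.start},{self.end})")


@dataclass
class Document:
    doc_id: str
    text: str
    title: str = ""
    tokens: list[Token] = field(default_factory=list)
    # sentence i covers tokens[sentences[i][0]:sentences[i][1]]
    sentences: list[tuple[int, int]] = field(default_factory=list)

    def sentence_tokens(self, i: int) -> list[Token]:
        a, b = self.sentences[i]
        return self.tokens[a:b]

    def sentence_span(self, i: int) -> tuple[int, int]:
        toks = self.sentence_tokens(i)
        return (toks[0].start, toks[-1].end) if toks else (0, 0)

    def validate(self) -> None:
        prev_end = -1
        for t in self.tokens:
            if t.end > len(self.text):
                raise CorpusError(
                    f"{self.doc_id}: token ({t.start},{t.end}) beyond text")
            if self.text[t.start:t.end] != t.text:
                raise CorpusError(
                    f"{self.doc_id}: token text mismatch at {t.start}")
            if t.start < prev_end:
                raise CorpusError(
                    f"{self.doc_id}: overlapping tokens at {t.start}")
            prev_end = t.end
        covered = 0
        for a, b in self.sentences:
            if a != covered:
                raise CorpusError(f"{self.doc_id}: sentence ranges do not partition tokens")
            covered = b
        if covered != len(self.tokens):
            raise CorpusError(f"{self.doc_id}: sentence ranges do not partition tokens")


@dataclass(frozen=True)
class Mention:
    """A typed character span over a document's text."""

    doc_id: str
    start: int
    end: int
    surface: str
    rtype: str = UNSPECIFIED
    source: str = "gold"  # gold | dictionary | crf | postprocess

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CorpusError(
                f"{self.doc_id}: empty mention span ({self.start},{self.end})")
        if self.rtype not in RTYPES:
            raise CorpusError(f"{self.doc_id}: unknown rtype {self.rtype!r}")

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class LabelSequence:
    """Per-token B/I/O labels aligned to a document's token list."""

    doc_id: str
    labels: list[str]

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"B", "I", "O"}
        if bad:
            raise CorpusError(f"{self.doc_id}: invalid labels {bad}")


# ---------------------------------------------------------------------------
# Tokenisation / sentence splitting
# ---------------------------------------------------------------------------

# Identifier-preserving mode keeps database accession patterns such as
# "GO:0007089" as a single token.  Database identifiers are not resource
# names, and splitting them exposes the leading prefix ("GO") to spurious
# dictionary hits; keeping them whole removes that failure mode at source.
_IDENT = r"[A-Za-z][A-Za-z0-9]*:\d+"
_DECIMAL = r"\d+(?:\.\d+)+"
_WORD = r"[A-Za-z]+(?:'[A-Za-z]+)?"
_NUM = r"\d+"

_TOKEN_RE_ID = re.compile(f"{_IDENT}|{_DECIMAL}|{_WORD}|{_NUM}|\\S")
_TOKEN_RE_PLAIN = re.compile(f"{_DECIMAL}|{_WORD}|{_NUM}|\\S")

_SENT_END = {".", "!", "?"}


def tokenize(text: str, preserve_identifiers: bool = True
             ) -> tuple[list[Token], list[tuple[int, int]]]:
    """Tokenise and sentence-split ``text``.

    Tokens are maximal runs of letters, digit runs (decimals such as
    "1.83" kept whole), or single other characters; every non-whitespace
    character belongs to exactly one token.  With ``preserve_identifiers``
    (default), prefix:number identifiers like "GO:0007089" stay one token.

    Returns the token list (without POS/lemma) and sentence index ranges.
    Raises :class:`CorpusError` on empty/whitespace-only text.
    """
    if not text or not text.strip():
        raise CorpusError("cannot tokenize empty text")
    rx = _TOKEN_RE_ID if preserve_identifiers else _TOKEN_RE_PLAIN
    raw = [(m.group(), m.start(), m.end()) for m in rx.finditer(text)]
    tokens: list[Token] = []
    sentences: list[tuple[int, int]] = []
    sent_start = 0
    sent_idx = 0
    for k, (tok, a, b) in enumerate(raw):
        tokens.append(Token(tok, a, b, sent_index=sent_idx))
        if tok in _SENT_END:
            # close a sentence unless the next token continues punctuation
            nxt = raw[k + 1][0] if k + 1 < len(raw) else None
            if nxt is None or nxt not in _SENT_END:
                sentences.append((sent_start, k + 1))
                sent_start = k + 1
                sent_idx += 1
    if sent_start < len(tokens):
        sentences.append((sent_start, len(tokens)))
    return tokens, sentences


# ---------------------------------------------------------------------------
# POS tagging and lemmatisation (heuristic Penn-tagset provider)
# ---------------------------------------------------------------------------

_DT = {"the", "a", "an", "this", "that", "these", "those", "each", "every"}
_IN = {"of", "in", "on", "for", "with", "from", "to", "by", "at", "as",
       "against", "between", "within", "during", "after", "before", "than"}
_CC = {"and", "or", "but", "nor"}
_PRP = {"we", "it", "they", "he", "she", "i", "you"}
_MD = {"can", "could", "may", "might", "must", "shall", "should", "will", "would"}
_BE = {"is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
       "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD", "does": "VBZ",
       "do": "VBP", "did": "VBD"}
_COMMON_VERBS = {"use", "run", "ran", "provide", "allow", "compare", "compared",
                 "generate", "obtain", "perform", "apply", "applied", "process",
                 "implement", "implemented", "download", "downloaded", "install",
                 "evaluate", "analyse", "analysed", "simulate", "contain",
                 "contains", "contained", "used", "using"}


def pos_tag(token: str, is_sentence_initial: bool = False) -> str:
    """Heuristic Penn Treebank tag for a single token.

    Deliberately simple: proper nouns (NNP) for capitalised or
    mixed-case/digit-bearing name-like tokens, CD for numbers, closed-class
    lists for function words, suffix rules for the rest.
    """
    low = token.lower()
    if not any(c.isalnum() for c in token):
        return token if len(token) == 1 else "SYM"
    if re.fullmatch(r"\d+(\.\d+)*", token):
        return "CD"
    if low in _DT:
        return "DT"
    if low in _IN:
        return "IN"
    if low in _CC:
        return "CC"
    if low in _PRP:
        return "PRP"
    if low in _MD:
        return "MD"
    if low in _BE:
        return _BE[low]
    if any(c.isdigit() for c in token):
        return "NNP"  # digit-bearing names: S4, t2prhd
    if token.islower():
        if low in _COMMON_VERBS:
            if low.endswith("ing"):
                return "VBG"
            if low.endswith("ed"):
                return "VBD"
            if low.endswith("s"):
                return "VBZ"
            return "VB"
        if low.endswith("ly"):
            return "RB"
        if low.endswith("ing"):
            return "VBG"
        if low.endswith("s") and len(low) > 3:
            return "NNS"
        return "NN"
    # capitalised / all-caps / mixed case
    if is_sentence_initial and token[0].isupper() and token[1:].islower() \
            and low in _DT | _IN | _CC | _PRP:
        return "DT"
    return "NNP"


def lemmatize(token: str, pos: str) -> str:
    low = token.lower()
    if pos in ("NNS",) and low.endswith("s") and len(low) > 3:
        if low.endswith("ies"):
            return low[:-3] + "y"
        if not low.endswith("ss"):
            return low[:-1]
    if pos == "VBG" and low.endswith("ing") and len(low) > 5:
        return low[:-3]
    if pos == "VBD" and low.endswith("ed") and len(low) > 4:
        return low[:-2]
    if pos == "VBZ" and low.endswith("s") and len(low) > 3:
        return low[:-1]
    return low


def make_document(doc_id: str, text: str, title: str = "",
                  preserve_identifiers: bool = True) -> Document:
    """Tokenise, sentence-split, POS-tag and lemmatise ``text``."""
    tokens, sentences = tokenize(text, preserve_identifiers=preserve_identifiers)
    sent_starts = {a for a, _ in sentences}
    out: list[Token] = []
    for k, t in enumerate(tokens):
        pos = pos_tag(t.text, is_sentence_initial=(k in sent_starts))
        out.append(replace(t, pos=pos, lemma=lemmatize(t.text, pos)))
    doc = Document(doc_id=doc_id, text=text, title=title,
                   tokens=out, sentences=sentences)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# B-I-O conversion
# ---------------------------------------------------------------------------

def mentions_to_bio(doc: Document, mentions: Sequence[Mention]) -> LabelSequence:
    """Project character-span mentions onto per-token B-I-O labels.

    Mentions must be non-overlapping.  A mention boundary that falls inside
    a token is snapped outward to the covering tokens (never dropped), with
    a logged warning — widening preserves recall accounting.
    """
    ms = sorted(mentions, key=lambda m: m.start)
    for a, b in zip(ms, ms[1:]):
        if a.overlaps(b):
            raise CorpusError(
                f"{doc.doc_id}: overlapping mentions at {a.start} and {b.start}")
    labels = ["O"] * len(doc.tokens)
    for m in ms:
        if m.end > len(doc.text):
            raise CorpusError(
                f"{doc.doc_id}: mention ({m.start},{m.end}) beyond text")
        idx = [k for k, t in enumerate(doc.tokens)
               if t.start < m.end and m.start < t.end]
        if not idx:
            logger.warning("%s: mention (%d,%d) %r covers no token; skipped",
                           doc.doc_id, m.start, m.end, m.surface)
            continue
        first, last = idx[0], idx[-1]
        if doc.tokens[first].start != m.start or doc.tokens[last].end != m.end:
            logger.warning(
                "%s: mention (%d,%d) %r not token-aligned; snapped outward to "
                "(%d,%d)", doc.doc_id, m.start, m.end, m.surface,
                doc.tokens[first].start, doc.tokens[last].end)
        labels[first] = "B"
        for k in idx[1:]:
            labels[k] = "I"
    return LabelSequence(doc_id=doc.doc_id, labels=labels)


def bio_to_mentions(doc: Document, seq: LabelSequence,
                    source: str = "crf") -> list[Mention]:
    """Decode maximal B(I)* runs into character-span mentions."""
    if len(seq.labels) != len(doc.tokens):
        raise CorpusError(
            f"{doc.doc_id}: {len(seq.labels)} labels for {len(doc.tokens)} tokens")
    mentions: list[Mention] = []
    k = 0
    n = len(doc.tokens)
    while k < n:
        if seq.labels[k] in ("B", "I"):  # I-initial run tolerated (repaired upstream)
            j = k + 1
            while j < n and seq.labels[j] == "I":
                j += 1
            start = doc.tokens[k].start
            end = doc.tokens[j - 1].end
            mentions.append(Mention(doc.doc_id, start, end,
                                    doc.text[start:end], source=source))
            k = j
        else:
            k += 1
    return mentions


# ---------------------------------------------------------------------------
# Standoff (brat-style) I/O
# ---------------------------------------------------------------------------

_RTYPE_TO_ANN = {DATABASE: "Database", SOFTWARE: "Software",
                 UNSPECIFIED: "Resource"}
_ANN_TO_RTYPE = {"Database": DATABASE, "Software": SOFTWARE,
                 "Resource": UNSPECIFIED}


def read_standoff(corpus_dir: str | Path, preserve_identifiers: bool = True
                  ) -> list[tuple[Document, list[Mention]]]:
    """Load paired ``.txt``/``.ann`` files from a directory.

    The ``.ann`` dialect is brat's entity line:
    ``T<k>\\t<Type> <start> <end>\\t<surface>``.  All mention invariants are
    verified on load; a violation raises :class:`CorpusError` naming the
    file and offset.
    """
    corpus_dir = Path(corpus_dir)
    out: list[tuple[Document, list[Mention]]] = []
    txts = sorted(corpus_dir.glob("*.txt"))
    if not txts:
        raise CorpusError(f"no .txt files in {corpus_dir}")
    for txt in txts:
        text = txt.read_text(encoding="utf-8")
        title = ""
        title_file = txt.with_suffix(".title")
        if title_file.exists():
            title = title_file.read_text(encoding="utf-8").strip()
        doc = make_document(txt.stem, text, title=title,
                            preserve_identifiers=preserve_identifiers)
        ann = txt.with_suffix(".ann")
        mentions: list[Mention] = []
        if ann.exists():
            for ln, line in enumerate(ann.read_text(encoding="utf-8").splitlines(), 1):
                if not line.strip() or not line.startswith("T"):
                    continue
                try:
                    _, meta, surface = line.split("\t", 2)
                    atype, s, e = meta.split()
                    start, end = int(s), int(e)
                except ValueError as exc:
                    raise CorpusError(f"{ann.name}:{ln}: malformed line") from exc
                if end > len(text):
                    raise CorpusError(
                        f"{ann.name}:{ln}: offset {end} beyond text length {len(text)}")
                if text[start:end] != surface:
                    raise CorpusError(
                        f"{ann.name}:{ln}: surface mismatch at ({start},{end})")
                mentions.append(Mention(doc.doc_id, start, end, surface,
                                        rtype=_ANN_TO_RTYPE.get(atype, UNSPECIFIED),
                                        source="gold"))
        mentions.sort(key=lambda m: m.start)
        for a, b in zip(mentions, mentions[1:]):
            if a.overlaps(b):
                raise CorpusError(
                    f"{ann.name}: overlapping gold mentions at {a.start}/{b.start}")
        out.append((doc, mentions))
    return out


def write_standoff(corpus: Iterable[tuple[Document, Sequence[Mention]]],
                   out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc, mentions in corpus:
        (out_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        if doc.title:
            (out_dir / f"{doc.doc_id}.title").write_text(doc.title + "\n",
                                                         encoding="utf-8")
        lines = []
        for k, m in enumerate(sorted(mentions, key=lambda m: m.start), 1):
            lines.append(f"T{k}\t{_RTYPE_TO_ANN[m.rtype]} {m.start} {m.end}\t{m.surface}")
        (out_dir / f"{doc.doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON-lines interchange
# ---------------------------------------------------------------------------

def write_jsonl(corpus: Iterable[tuple[Document, Sequence[Mention]]],
                path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc, mentions in corpus:
            rec = {"doc_id": doc.doc_id, "title": doc.title, "text": doc.text,
                   "mentions": [{"start": m.start, "end": m.end,
                                 "rtype": m.rtype, "source": m.source}
                                for m in mentions]}
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path: str | Path, preserve_identifiers: bool = True
               ) -> list[tuple[Document, list[Mention]]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            doc = make_document(rec["doc_id"], rec["text"],
                                title=rec.get("title", ""),
                                preserve_identifiers=preserve_identifiers)
            mentions = [Mention(doc.doc_id, m["start"], m["end"],
                                doc.text[m["start"]:m["end"]],
                                rtype=m.get("rtype", UNSPECIFIED),
                                source=m.get("source", "gold"))
                        for m in rec.get("mentions", [])]
            out.append((doc, mentions))
    return out


# ---------------------------------------------------------------------------
# CoNLL-style export
# ---------------------------------------------------------------------------

def write_conll(doc: Document, seq: LabelSequence,
                features: Sequence[Sequence[str]] | None = None) -> str:
    """Serialise one token per line (token, POS, [features...], label),
    tab-separated, with a blank line after each sentence."""
    if len(seq.labels) != len(doc.tokens):
        raise CorpusError(
            f"{doc.doc_id}: {len(seq.labels)} labels for {len(doc.tokens)} tokens")
    lines: list[str] = []
    for si, (a, b) in enumerate(doc.sentences):
        for k in range(a, b):
            t = doc.tokens[k]
            cols = [t.text, t.pos]
            if features is not None:
                cols.extend(features[k])
            cols.append(seq.labels[k])
            lines.append("\t".join(cols))
        lines.append("")
    return "\n".join(lines) + "\n"


def read_conll(text: str) -> list[list[tuple[str, str, str]]]:
    """Parse CoNLL export back into sentences of (token, pos, label)."""
    sentences: list[list[tuple[str, str, str]]] = []
    cur: list[tuple[str, str, str]] = []
    for line in text.splitlines():
        if not line.strip():
            if cur:
                sentences.append(cur)
                cur = []
            continue
        cols = line.split("\t")
        cur.append((cols[0], cols[1], cols[-1]))
    if cur:
        sentences.append(cur)
    return sentences
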