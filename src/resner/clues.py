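"""Rule-based textual clue detectors for database/software mentions.

Resource names that no dictionary or trained model knows yet are often
introduced alongside characteristic context: an explicit head term ("the
MethMarker software"), a Hearst-style enumeration ("programs such as
Simlink, ..., and SimPed"), a "Name: description" paper title, versioning
("CLUSTAL W version 1.83"), a trailing citation or URL ("Galaxy [18]"),
or a comparison between tools ("Foldalign was much slower than Cofolga2").
Each detector here is a pure function of a sentence (or title) emitting
:class:`ClueMatch` records with the clue span and, when one can be
anchored, a candidate name span.

Candidate anchoring uses a "name-shaped" token filter: runs of up to four
tokens that are capitalised, all-caps, mixed-case with an internal
capital, or letter+digit; a single lowercase one-letter token is admitted
inside a run when a name-shaped token follows it (e.g. "i Linker").

The module also computes the clue–mention sentence co-occurrence
statistic: of the sentences matching a clue regex, what fraction contain a
gold mention (and the reverse).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Document, Mention, Token

CLUE_CATEGORIES = ("head", "hearst", "title", "ref_url", "version",
                   "assoc_expression", "comparison")

#: explicit resource-type designators
HEAD_TERMS = ("database", "software", "tool", "program", "simulator",
              "system", "library", "service", "package", "webserver")

#: cue phrases for tool-to-tool comparisons (token-level, lowercased)
COMPARISON_CUES = (("better", "than"), ("worse", "than"), ("slower", "than"),
                   ("faster", "than"), ("compared", "to"), ("compared", "with"),
                   ("equal", "to"), ("similar", "to"))

#: units that disqualify a bare "Name 1.8"-style version reading
_UNIT_TOKENS = {"ghz", "mhz", "hz", "gb", "mb", "kb", "tb", "bp", "nt", "aa",
                "%", "s", "ms", "min", "h", "nm", "mm", "cm", "m", "km", "kg",
                "g", "mg", "ml", "l"}

_TITLE_STOP_WORDS = {"method", "methods", "algorithm", "algorithms"}

_MAX_NAME_TOKENS = 4


@dataclass(frozen=True)
class ClueMatch:
    doc_id: str
    sent_index: int
    category: str  # one of CLUE_CATEGORIES
    clue_start: int
    clue_end: int
    clue_text: str
    candidate_start: int | None = None
    candidate_end: int | None = None
    candidate_text: str | None = None


@dataclass
class ClueStats:
    """Sentence-level co-occurrence of a clue regex with gold mentions."""

    pattern: str
    n_clue_sentences: int
    n_clue_sentences_with_mention: int
    n_mention_sentences: int
    n_mention_sentences_with_clue: int
    no_clue_sentences: bool = False  # flag: regex matched nothing

    @property
    def forward_fraction(self) -> float:
        """P(mention in sentence | clue in sentence)."""
        if not self.n_clue_sentences:
            return 0.0
        return self.n_clue_sentences_with_mention / self.n_clue_sentences

    @property
    def reverse_fraction(self) -> float:
        """P(clue in sentence | mention in sentence)."""
        if not self.n_mention_sentences:
            return 0.0
        return self.n_mention_sentences_with_clue / self.n_mention_sentences


# ---------------------------------------------------------------------------
# Name-shaped token runs
# ---------------------------------------------------------------------------

#: capitalised function/common words excluded from candidate runs
_RUN_STOPS = {"the", "a", "an", "we", "in", "on", "of", "this", "that",
              "these", "those", "like", "as", "such", "and", "or", "but",
              "for", "with", "to", "from", "it", "its", "our", "their"}


def is_name_shaped(token: str) -> bool:
    """Capitalised, all-caps, mixed-case with an internal capital, or a
    letters+digits composite.  Capitalised function words ("The", "We")
    are excluded — sentence-initial capitalisation is not a name cue."""
    if not token or not token[0].isalnum():
        return False
    if token.lower() in _RUN_STOPS:
        return False
    has_upper = any(c.isupper() for c in token)
    has_digit = any(c.isdigit() for c in token)
    has_alpha = any(c.isalpha() for c in token)
    if token[0].isupper():
        return True
    if has_upper:  # internal capital: mixed case like "eUtils"
        return True
    return has_digit and has_alpha  # t2prhd, v1


def _run_right(tokens: Sequence[Token], start: int) -> tuple[int, int] | None:
    """Longest name-shaped run beginning at ``start`` (token indices,
    half-open)."""
    j = start
    while j < len(tokens) and j - start < _MAX_NAME_TOKENS:
        t = tokens[j].text
        if is_name_shaped(t):
            j += 1
        elif (t.islower() and len(t) == 1 and j + 1 < len(tokens)
              and is_name_shaped(tokens[j + 1].text)):
            j += 1  # "i Linker": 1-letter lowercase admitted mid-run
        else:
            break
    return (start, j) if j > start else None


def _run_left(tokens: Sequence[Token], end: int) -> tuple[int, int] | None:
    """Longest name-shaped run ending just before ``end``."""
    i = end
    while i > 0 and end - i < _MAX_NAME_TOKENS:
        t = tokens[i - 1].text
        if is_name_shaped(t):
            i -= 1
        elif (t.islower() and len(t) == 1 and i < end
              and is_name_shaped(tokens[i].text)):
            i -= 1
        else:
            break
    # trim a leading lowercase helper with nothing after it
    return (i, end) if i < end else None


def _span_of(doc: Document, tokens: Sequence[Token], i: int, j: int
             ) -> tuple[int, int, str]:
    start, end = tokens[i].start, tokens[j - 1].end
    return start, end, doc.text[start:end]


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_head_terms(doc: Document, sent_index: int) -> list[ClueMatch]:
    """Head-term clues: a resource-type designator with, when present, the
    adjacent name-shaped run on its non-head side as candidate —
    "the stochastic simulator Dizzy" (candidate right), "The MethMarker
    software" (candidate left)."""
    toks = doc.sentence_tokens(sent_index)
    out: list[ClueMatch] = []
    for k, t in enumerate(toks):
        low = t.text.lower()
        if low.rstrip("s") not in HEAD_TERMS and low not in HEAD_TERMS:
            continue
        cand = _run_right(toks, k + 1) or _run_left(toks, k)
        kw = dict(doc_id=doc.doc_id, sent_index=sent_index, category="head",
                  clue_start=t.start, clue_end=t.end, clue_text=t.text)
        if cand:
            cs, ce, ct = _span_of(doc, toks, *cand)
            out.append(ClueMatch(candidate_start=cs, candidate_end=ce,
                                 candidate_text=ct, **kw))
        else:
            out.append(ClueMatch(**kw))
    return out


def detect_hearst(doc: Document, sent_index: int) -> list[ClueMatch]:
    """Enumeration patterns: "<head>s: A, B, ..., and C" and "<head>s such
    as A, ..., and C" yield every list member as a candidate."""
    toks = doc.sentence_tokens(sent_index)
    out: list[ClueMatch] = []
    for k, t in enumerate(toks):
        low = t.text.lower()
        if not (low.endswith("s") and low.rstrip("s") in HEAD_TERMS):
            continue
        # locate the start of the enumeration
        start = None
        if k + 1 < len(toks) and toks[k + 1].text == ":":
            start = k + 2
        elif (k + 2 < len(toks) and toks[k + 1].text.lower() == "such"
              and toks[k + 2].text.lower() == "as"):
            start = k + 3
        if start is None:
            continue
        members: list[tuple[int, int]] = []
        j = start
        while j < len(toks):
            run = _run_right(toks, j)
            if run is None:
                break
            members.append(run)
            j = run[1]
            # skip list separators: "," | ", and" | "and" | ellipses
            while j < len(toks) and toks[j].text in (",", "…", "."):
                j += 1
                if j <= len(toks) and toks[j - 1].text == ".":
                    j = len(toks)  # sentence end reached
                    break
            if j < len(toks) and toks[j].text.lower() == "and":
                j += 1
        for i0, j0 in members:
            cs, ce, ct = _span_of(doc, toks, i0, j0)
            out.append(ClueMatch(doc_id=doc.doc_id, sent_index=sent_index,
                                 category="hearst", clue_start=t.start,
                                 clue_end=t.end, clue_text=t.text,
                                 candidate_start=cs, candidate_end=ce,
                                 candidate_text=ct))
    return out


_TITLE_RE = re.compile(r"^\s*(?P<name>[^:]{1,80}?)\s*:\s+\S")


def detect_title_pattern(title: str) -> str | None:
    """"<Name>: <description>" titles that introduce a resource.

    The pre-colon part must be at most four tokens, every token
    name-shaped, and must not contain "method(s)"/"algorithm(s)" — those
    titles tend to introduce procedures, not resources.
    """
    if not title:
        return None
    m = _TITLE_RE.match(title)
    if not m:
        return None
    name = m.group("name").strip()
    toks = name.split()
    if not 1 <= len(toks) <= _MAX_NAME_TOKENS:
        return None
    if any(t.lower() in _TITLE_STOP_WORDS for t in toks):
        return None
    if not all(is_name_shaped(t) for t in toks):
        return None
    return name


_VNUM = re.compile(r"v\d+(?:\.\d+)*$", re.IGNORECASE)
_NUM = re.compile(r"\d+(?:\.\d+)+$")
_VERSION_STOPS = {"the", "a", "an", "using", "used", "with", "in", "of", "to",
                  "and", "or", "at", "on", "by", "from", "for", "is", "was"}


def detect_version(doc: Document, sent_index: int) -> list[ClueMatch]:
    """Version clues next to a name-shaped run: "<Name> v1.10",
    "<Name> version 1.83", "<Name> 4.5".  The bare-number form is
    suppressed when a measurement unit follows (an "AMD Athlon 1.8 GHz"
    is hardware, not a release)."""
    toks = doc.sentence_tokens(sent_index)
    out: list[ClueMatch] = []
    for k, t in enumerate(toks):
        ver_span = None  # (clue_first_idx, clue_last_idx, version string)
        explicit = False  # carries a "v"/"version" marker
        if _VNUM.fullmatch(t.text) and len(t.text) > 1:
            ver_span, explicit = (k, k, t.text[1:]), True
        elif (t.text.lower() in ("v", "version") and k + 1 < len(toks)
              and re.fullmatch(r"\d+(\.\d+)*", toks[k + 1].text)):
            ver_span, explicit = (k, k + 1, toks[k + 1].text), True
        elif _NUM.fullmatch(t.text):
            nxt = toks[k + 1].text.lower() if k + 1 < len(toks) else None
            if nxt not in _UNIT_TOKENS:
                ver_span = (k, k, t.text)
        if ver_span is None:
            continue
        left = _run_left(toks, ver_span[0])
        if left is None and explicit:
            # an unambiguous version marker licenses a lowercase name
            # ("using dot v1.10"), which the shape filter alone would drop
            p = ver_span[0] - 1
            if p >= 0 and toks[p].text.isalpha() and \
                    toks[p].text.lower() not in _VERSION_STOPS:
                left = (p, ver_span[0])
        if left is None:
            continue
        # the run must not itself be a version token
        cs, ce, ct = _span_of(doc, toks, *left)
        if _VNUM.fullmatch(ct) or _NUM.fullmatch(ct):
            continue
        clue_start = toks[ver_span[0]].start
        clue_end = toks[ver_span[1]].end
        out.append(ClueMatch(doc_id=doc.doc_id, sent_index=sent_index,
                             category="version", clue_start=clue_start,
                             clue_end=clue_end,
                             clue_text=doc.text[clue_start:clue_end],
                             candidate_start=cs, candidate_end=ce,
                             candidate_text=ct))
    return out


_URL_RE = re.compile(r"^(https?://|www\.)", re.IGNORECASE)


def detect_ref_url(doc: Document, sent_index: int) -> list[ClueMatch]:
    """A name-shaped token run immediately before a "[<digits>]" citation
    or a URL.  Non-name-shaped left context ("principle [14, 15]") is
    rejected by the shape filter."""
    toks = doc.sentence_tokens(sent_index)
    out: list[ClueMatch] = []
    for k, t in enumerate(toks):
        is_ref = (t.text == "[" and k + 2 < len(toks)
                  and toks[k + 1].text.isdigit() and toks[k + 2].text in ("]", ","))
        # URLs are split by the tokeniser, so the scheme/host prefix token
        # marks the clue
        is_url = bool(_URL_RE.match(t.text)) or \
            t.text.lower() in ("http", "https", "www")
        if not (is_ref or is_url):
            continue
        left = _run_left(toks, k)
        if left is None:
            continue
        cs, ce, ct = _span_of(doc, toks, *left)
        if not any(c.isupper() or c.isdigit() for c in ct):
            continue
        clue_end = toks[k + 2].end if is_ref else t.end
        out.append(ClueMatch(doc_id=doc.doc_id, sent_index=sent_index,
                             category="ref_url", clue_start=t.start,
                             clue_end=clue_end,
                             clue_text=doc.text[t.start:clue_end],
                             candidate_start=cs, candidate_end=ce,
                             candidate_text=ct))
    return out


def detect_comparison(doc: Document, sent_index: int) -> list[ClueMatch]:
    """Comparisons between tools: cue phrases ("better than", "compared
    to", "slower than", "equal to", ...) with name-shaped runs on both
    sides, and the sentence-initial "Like X, Y ..." frame.  Emits one
    ClueMatch per side of each detected pair."""
    toks = doc.sentence_tokens(sent_index)
    out: list[ClueMatch] = []

    def emit(cue_first: Token, cue_last: Token,
             left: tuple[int, int], right: tuple[int, int]) -> None:
        for run in (left, right):
            cs, ce, ct = _span_of(doc, toks, *run)
            out.append(ClueMatch(
                doc_id=doc.doc_id, sent_index=sent_index, category="comparison",
                clue_start=cue_first.start, clue_end=cue_last.end,
                clue_text=doc.text[cue_first.start:cue_last.end],
                candidate_start=cs, candidate_end=ce, candidate_text=ct))

    for k in range(len(toks) - 1):
        pair = (toks[k].text.lower(), toks[k + 1].text.lower())
        if pair not in COMPARISON_CUES:
            continue
        # left run may be separated from the cue by a short verb phrase
        left = None
        for back in range(0, 4):
            if k - back <= 0:
                break
            left = _run_left(toks, k - back)
            if left:
                break
        right = _run_right(toks, k + 2)
        if left and right:
            emit(toks[k], toks[k + 1], left, right)

    # "Like X, Y ..." frame
    if toks and toks[0].text.lower() == "like":
        first = _run_right(toks, 1)
        if first:
            j = first[1]
            if j < len(toks) and toks[j].text == ",":
                second = _run_right(toks, j + 1)
                if second:
                    emit(toks[0], toks[0], first, second)
    return out


def detect_all(doc: Document) -> list[ClueMatch]:
    """Every sentence-level detector over every sentence, plus the title
    pattern."""
    out: list[ClueMatch] = []
    for si in range(len(doc.sentences)):
        out.extend(detect_head_terms(doc, si))
        out.extend(detect_hearst(doc, si))
        out.extend(detect_version(doc, si))
        out.extend(detect_ref_url(doc, si))
        out.extend(detect_comparison(doc, si))
    name = detect_title_pattern(doc.title)
    if name is not None:
        pos = doc.title.find(name)
        out.append(ClueMatch(doc_id=doc.doc_id, sent_index=-1, category="title",
                             clue_start=pos, clue_end=pos + len(name),
                             clue_text=name, candidate_start=pos,
                             candidate_end=pos + len(name),
                             candidate_text=name))
    return out


# ---------------------------------------------------------------------------
# Clue–mention co-occurrence
# ---------------------------------------------------------------------------

def clue_cooccurrence(corpus: Sequence[tuple[Document, Sequence[Mention]]],
                      pattern: str) -> ClueStats:
    """How discriminative a clue regex is at sentence level.

    Forward: of sentences matching the regex, the fraction containing at
    least one gold mention.  Reverse: of sentences containing a mention,
    the fraction matching the regex.  A regex matching no sentence is
    flagged and reports 0 fractions.
    """
    rx = re.compile(pattern)
    n_clue = n_clue_with = n_ment = n_ment_with = 0
    for doc, mentions in corpus:
        for si in range(len(doc.sentences)):
            a, b = doc.sentence_span(si)
            text = doc.text[a:b]
            has_clue = bool(rx.search(text))
            has_mention = any(m.start < b and a < m.end for m in mentions)
            n_clue += has_clue
            n_clue_with += has_clue and has_mention
            n_ment += has_mention
            n_ment_with += has_mention and has_clue
    return ClueStats(pattern=pattern, n_clue_sentences=n_clue,
                     n_clue_sentences_with_mention=n_clue_with,
                     n_mention_sentences=n_ment,
                     n_mention_sentences_with_clue=n_ment_with,
                     no_clue_sentences=(n_clue == 0))


def clue_report_tsv(matches: Iterable[ClueMatch]) -> str:
    lines = ["doc_id\tsent_index\tcategory\tclue\tcandidate"]
    for m in matches:
        lines.append(f"{m.doc_id}\t{m.sent_index}\t{m.category}\t"
                     f"{m.clue_text}\t{m.candidate_text or ''}")
    return "\n".join(lines) + "\n"
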