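"""Descriptive analytics over annotated corpora and resource dictionaries.

Covers the quantities used to characterise how databases and software are
named and mentioned: per-corpus mention statistics (totals, lexically
unique surfaces, per-document means, singletons), Porter-stemmed token
frequencies over name inventories, internal POS-pattern profiles of names,
and name variability (mean variants per resource).

"Lexically unique" means distinct exact surface strings, case-sensitive:
"BLAST" and "blast" are two surfaces.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import DATABASE, Document, Mention
from .dictionary import ResourceDictionary

logger = logging.getLogger("resner")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the [C](VC)^m[V] decomposition."""
    forms = ""
    for i in range(len(stem)):
        forms += "c" if _cons(stem, i) else "v"
    m = 0
    prev = None
    for ch in forms:
        if prev == "v" and ch == "c":
            m += 1
        prev = ch
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _cons(stem, i) for i in range(len(stem)))


def _double_cons(word: str) -> bool:
    return (len(word) >= 2 and word[-1] == word[-2] and _cons(word, len(word) - 1))


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (_cons(word, len(word) - 3) and not _cons(word, len(word) - 2)
            and _cons(word, len(word) - 1)):
        return False
    return word[-1] not in "wxy"


def porter_stem(word: str) -> str:
    """The classic Porter stemming algorithm (steps 1–5) over a lowercased
    word.  Non-alphabetic tokens are returned lowercased unchanged."""
    w = word.lower()
    if len(w) <= 2 or not w.isalpha():
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    flag_1b = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        flag_1b = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        flag_1b = True
    if flag_1b:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _double_cons(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _cvc(w):
            w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suf, rep in (("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
                     ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
                     ("alli", "al"), ("entli", "ent"), ("eli", "e"),
                     ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
                     ("ator", "ate"), ("alism", "al"), ("iveness", "ive"),
                     ("fulness", "ful"), ("ousness", "ous"), ("aliti", "al"),
                     ("iviti", "ive"), ("biliti", "ble")):
        if w.endswith(suf):
            if _measure(w[:-len(suf)]) > 0:
                w = w[:-len(suf)] + rep
            break

    # step 3
    for suf, rep in (("icate", "ic"), ("ative", ""), ("alize", "al"),
                     ("iciti", "ic"), ("ical", "ic"), ("ful", ""), ("ness", "")):
        if w.endswith(suf):
            if _measure(w[:-len(suf)]) > 0:
                w = w[:-len(suf)] + rep
            break

    # step 4
    for suf in ("al", "ance", "ence", "er", "ic", "able", "ible", "ant",
                "ement", "ment", "ent", "ion", "ou", "ism", "ate", "iti",
                "ous", "ive", "ize"):
        if w.endswith(suf):
            stem = w[:-len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                break
            if _measure(stem) > 1:
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem
    # step 5b
    if _measure(w) > 1 and _double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


# ---------------------------------------------------------------------------
# Corpus summary
# ---------------------------------------------------------------------------

@dataclass
class CorpusSummary:
    n_docs: int
    total_mentions: int
    unique_surface_mentions: int
    mean_mentions_per_doc: float
    mean_unique_per_doc: float
    max_mentions_single_doc: int
    max_unique_single_doc: int
    singleton_surface_count: int
    db_mention_fraction: float | None = None

    @property
    def singleton_fraction(self) -> float:
        """Share of lexically unique surfaces occurring exactly once,
        as a percentage."""
        return 100.0 * self.singleton_surface_count / self.unique_surface_mentions

    def as_dict(self) -> dict:
        d = {"n_docs": self.n_docs, "total_mentions": self.total_mentions,
             "unique_surface_mentions": self.unique_surface_mentions,
             "mean_mentions_per_doc": round(self.mean_mentions_per_doc, 1),
             "mean_unique_per_doc": round(self.mean_unique_per_doc, 1),
             "max_mentions_single_doc": self.max_mentions_single_doc,
             "max_unique_single_doc": self.max_unique_single_doc,
             "singleton_surface_count": self.singleton_surface_count,
             "singleton_fraction_pct": round(self.singleton_fraction)}
        if self.db_mention_fraction is not None:
            d["db_mention_fraction_pct"] = round(100 * self.db_mention_fraction)
        return d


def _surfaces_by_doc(corpus) -> dict[str, list[object]]:
    """Accept either a list of (Document, mentions) pairs or a mapping
    doc_id → mention list (mentions may be Mention objects or plain
    surface strings)."""
    if isinstance(corpus, Mapping):
        return {k: list(v) for k, v in corpus.items()}
    return {doc.doc_id: list(ms) for doc, ms in corpus}


def corpus_summary(corpus) -> CorpusSummary:
    """Mention statistics over a gold-annotated corpus.

    ``corpus`` is a list of (Document, mentions) pairs or a mapping
    doc_id → mentions, where each mention is a :class:`Mention` or a bare
    surface string.  Raises on an empty corpus.
    """
    by_doc = _surfaces_by_doc(corpus)
    if not by_doc:
        raise AnalysisError("empty corpus")

    def surf(m):
        return m.surface if isinstance(m, Mention) else str(m)

    def rtype(m):
        return m.rtype if isinstance(m, Mention) else None

    all_mentions = [m for ms in by_doc.values() for m in ms]
    surfaces = [surf(m) for m in all_mentions]
    counts = Counter(surfaces)
    per_doc_total = [len(ms) for ms in by_doc.values()]
    per_doc_unique = [len({surf(m) for m in ms}) for ms in by_doc.values()]
    typed = [rtype(m) for m in all_mentions if rtype(m) is not None]
    db_frac = (sum(1 for t in typed if t == DATABASE) / len(typed)
               if typed else None)
    n = len(by_doc)
    return CorpusSummary(
        n_docs=n,
        total_mentions=len(all_mentions),
        unique_surface_mentions=len(counts),
        mean_mentions_per_doc=len(all_mentions) / n,
        mean_unique_per_doc=sum(per_doc_unique) / n,
        max_mentions_single_doc=max(per_doc_total),
        max_unique_single_doc=max(per_doc_unique),
        singleton_surface_count=sum(1 for c in counts.values() if c == 1),
        db_mention_fraction=db_frac,
    )


# ---------------------------------------------------------------------------
# Lexical composition
# ---------------------------------------------------------------------------

def stem_token_frequency(names: Iterable[str]) -> list[tuple[str, int]]:
    """Porter-stem every whitespace token of every name and count stems.

    Ranked by descending count with a deterministic alphabetical tie-break.
    Empty-string names are skipped with a warning.
    """
    names = list(names)
    if not names:
        raise AnalysisError("empty name list")
    counts: Counter[str] = Counter()
    for name in names:
        if not name.strip():
            logger.warning("skipping empty name in stem frequency analysis")
            continue
        for tok in name.split():
            counts[porter_stem(tok)] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def name_length_histogram(names: Iterable[str]) -> dict[int, int]:
    """Distribution of name lengths in whitespace tokens."""
    hist: Counter[int] = Counter()
    for name in names:
        if name.strip():
            hist[len(name.split())] += 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# POS-pattern profile
# ---------------------------------------------------------------------------

def pos_pattern_profile(pairs: Iterable[tuple[str, str]]
                        ) -> list[tuple[str, int, float]]:
    """Profile the internal POS structure of names.

    ``pairs`` are (surface, pattern) observations, where the pattern is the
    space-joined POS tags over a mention's tokens.  Counting is over unique
    (surface, pattern) pairs, so one surface tagged two ways contributes
    two patterns.  Returns (pattern, count, percentage) ranked by
    descending count, alphabetical tie-break; percentages are of the total
    pattern count, to 1 decimal place.
    """
    uniq = {(s, p) for s, p in pairs}
    if not uniq:
        raise AnalysisError("no (surface, pattern) observations")
    counts = Counter(p for _, p in uniq)
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(p, c, round(100.0 * c / total, 1)) for p, c in ranked]


def mention_pos_pairs(corpus: Sequence[tuple[Document, Sequence[Mention]]]
                      ) -> list[tuple[str, str]]:
    """Extract (surface, POS pattern) pairs for every gold mention, using
    the tags of the tokens its span covers."""
    pairs: list[tuple[str, str]] = []
    for doc, mentions in corpus:
        for m in mentions:
            toks = [t for t in doc.tokens if t.start < m.end and m.start < t.end]
            if toks:
                pairs.append((m.surface, " ".join(t.pos for t in toks)))
    return pairs


# ---------------------------------------------------------------------------
# Variability
# ---------------------------------------------------------------------------

def variability_stats(grouping: ResourceDictionary | Mapping[str, Iterable[str]]
                      ) -> tuple[float, dict[int, int]]:
    """Mean unique variants per resource and the distribution of
    per-resource variant counts.

    Accepts a :class:`ResourceDictionary` (entries are the resources) or an
    explicit mapping resource → variant collection — at corpus level the
    grouping of surface forms into resources is supplied as input, since it
    requires background knowledge an algorithm does not have.

    The mean is computed as total unique variants (repeats across
    resources removed) over the number of resources, reported to 2 decimal
    places.
    """
    if isinstance(grouping, ResourceDictionary):
        per_resource = {e.canonical + f"#{i}": e.variants
                        for i, e in enumerate(grouping.entries)}
        n_unique = len(grouping.unique_variants())
    else:
        per_resource = {k: set(v) for k, v in grouping.items()}
        n_unique = len(set().union(*per_resource.values())) if per_resource else 0
    if not per_resource:
        raise AnalysisError("zero resources: variability undefined")
    dist: Counter[int] = Counter(len(v) for v in per_resource.values())
    mean = round(n_unique / len(per_resource), 2)
    return mean, dict(sorted(dist.items()))
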