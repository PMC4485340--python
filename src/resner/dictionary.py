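"""Resource-name dictionary: build, normalise, query, and tag documents.

The dictionary maps surface variants (e.g. "UniProt", "Uniprot", "GO",
"Gene Ontology") to canonical database (DB), software (SW) or package (PK)
entries.  Tagging is leftmost-longest matching on token boundaries with a
case policy tuned for short/acronym names, optional suppression of matches
inside database identifiers (``GO:0007089``), and optional document-local
expansion of abbreviations defined in text ("Long Form (SF)" pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import (DATABASE, SOFTWARE, UNSPECIFIED, Document, Mention)

# entry type codes in dictionary files
RTYPE_CODES = {"DB": DATABASE, "SW": SOFTWARE, "PK": SOFTWARE}


class DictionaryError(ValueError):
    """Raised for malformed dictionary files."""


def _norm_ws(s: str) -> str:
    """Whitespace normalisation used for variant identity and lookup."""
    return " ".join(s.split())


@dataclass
class DictionaryEntry:
    canonical: str
    rtype: str  # "DB" | "SW" | "PK"
    source: str = ""
    variants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.canonical.strip():
            raise DictionaryError("blank canonical name")
        if self.rtype not in RTYPE_CODES:
            raise DictionaryError(f"unknown rtype code {self.rtype!r}")
        self.variants = {_norm_ws(v) for v in self.variants if v.strip()}
        self.variants.add(_norm_ws(self.canonical))


class ResourceDictionary:
    """Indexed collection of :class:`DictionaryEntry`.

    ``variant_index`` maps the whitespace-normalised variant string to the
    ids of every entry carrying it; duplicate variants across entries are
    retained and flagged ambiguous rather than dropped.
    """

    def __init__(self, entries: Iterable[DictionaryEntry] = ()) -> None:
        self.entries: list[DictionaryEntry] = list(entries)
        self.variant_index: dict[str, list[int]] = {}
        # case-insensitive index, populated only for variants eligible for
        # case-insensitive matching (len > 4, not all-caps)
        self._ci_index: dict[str, list[int]] = {}
        self._token_vocab: set[str] = set()
        self._max_variant_chars = 0
        for eid, e in enumerate(self.entries):
            for v in e.variants:
                self.variant_index.setdefault(v, []).append(eid)
                if _ci_eligible(v):
                    self._ci_index.setdefault(v.lower(), []).append(eid)
                self._max_variant_chars = max(self._max_variant_chars, len(v))
                self._token_vocab.update(v.split())

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_resources(self) -> int:
        return len(self.entries)

    def unique_variants(self) -> set[str]:
        """All distinct variant strings after whitespace normalisation
        (repeats across entries removed)."""
        return set(self.variant_index)

    def all_names(self) -> set[str]:
        return self.unique_variants()

    def lookup(self, surface: str, case_sensitive_only: bool = False
               ) -> list[int]:
        """Entry ids whose variants match ``surface`` under the case policy."""
        s = _norm_ws(surface)
        ids = list(self.variant_index.get(s, ()))
        if not case_sensitive_only and not ids:
            ids = list(self._ci_index.get(s.lower(), ()))
        return ids

    def rtype_of(self, entry_ids: Sequence[int]) -> str:
        """Resolved mention type for a set of matched entries; UNSPECIFIED
        when matched entries disagree."""
        types = {RTYPE_CODES[self.entries[i].rtype] for i in entry_ids}
        return types.pop() if len(types) == 1 else UNSPECIFIED

    def contains_token(self, token: str) -> bool:
        """Dictionary feature rule: the token equals a variant or equals a
        whitespace-delimited token of a (multi-word) variant."""
        return token in self._token_vocab

    def without_entries(self, canonical_names: set[str]) -> "ResourceDictionary":
        return ResourceDictionary(
            e for e in self.entries if e.canonical not in canonical_names)


def _ci_eligible(variant: str) -> bool:
    """Case policy: variants of length <= 4 or all-caps match only
    case-sensitively; longer mixed-case variants also match
    case-insensitively.  Short names must stay case-sensitive because
    case-folding inflates collisions with common English words."""
    return len(variant) > 4 and not variant.isupper()


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_dictionary(path: str | Path) -> ResourceDictionary:
    """Load a delimited dictionary file.

    Each row is ``canonical<TAB>rtype<TAB>source<TAB>var1|var2|...`` or,
    alternatively, entirely pipe-delimited
    (``canonical|rtype|source|var1|var2``).  The canonical name is always a
    variant.  Lines starting with ``#`` and blank lines are skipped.
    """
    path = Path(path)
    entries: list[DictionaryEntry] = []
    for ln, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            parts = line.split("\t")
            if len(parts) < 3:
                raise DictionaryError(f"{path.name}:{ln}: expected >= 3 columns")
            canonical, rtype, source = parts[0], parts[1], parts[2]
            variants = parts[3].split("|") if len(parts) > 3 and parts[3] else []
        else:
            parts = line.split("|")
            if len(parts) < 3:
                raise DictionaryError(f"{path.name}:{ln}: expected >= 3 fields")
            canonical, rtype, source = parts[0], parts[1], parts[2]
            variants = parts[3:]
        try:
            entries.append(DictionaryEntry(canonical=canonical, rtype=rtype,
                                           source=source, variants=set(variants)))
        except DictionaryError as exc:
            raise DictionaryError(f"{path.name}:{ln}: {exc}") from exc
    return ResourceDictionary(entries)


def save_dictionary(d: ResourceDictionary, path: str | Path) -> None:
    lines = []
    for e in d.entries:
        variants = sorted(e.variants)
        lines.append("\t".join([e.canonical, e.rtype, e.source, "|".join(variants)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class MatchPolicy:
    """Toggles for the dictionary tagger.

    go_suppression
        Suppress a candidate match that is immediately followed in the raw
        text by ``:`` and a digit — a database identifier context such as
        "GO:0007089" (only reachable when identifier-splitting tokenisation
        is in use).  Default on.
    expand_abbreviations
        Detect "Long Form (SF)" definitions and, when the long form is a
        dictionary variant, add the short form as a document-local variant
        for a second matching pass.  Default on.
    case_insensitive_long
        Allow case-insensitive matching for long mixed-case variants
        (the case policy above).  Default on.
    """

    go_suppression: bool = True
    expand_abbreviations: bool = True
    case_insensitive_long: bool = True


def match(doc: Document, d: ResourceDictionary,
          policy: MatchPolicy | None = None) -> list[Mention]:
    """Leftmost-longest non-overlapping dictionary matches on token
    boundaries, ordered by start offset."""
    policy = policy or MatchPolicy()
    extra: dict[str, str] = {}
    if policy.expand_abbreviations:
        for (lf_start, lf_end), short in detect_abbreviations(doc):
            long_surface = _norm_ws(doc.text[lf_start:lf_end])
            ids = d.lookup(long_surface,
                           case_sensitive_only=not policy.case_insensitive_long)
            if ids:
                extra[_norm_ws(short)] = d.rtype_of(ids)
    return _match_tokens(doc, d, policy, extra)


def _match_tokens(doc: Document, d: ResourceDictionary, policy: MatchPolicy,
                  extra: Mapping[str, str]) -> list[Mention]:
    mentions: list[Mention] = []
    max_chars = max(d._max_variant_chars,
                    max((len(k) for k in extra), default=0))
    if max_chars == 0:
        return mentions
    for a, b in doc.sentences:
        i = a
        while i < b:
            hit = None
            # candidate spans are bounded by the longest variant in
            # characters (a one-word variant may cover several tokens,
            # e.g. letter+digit compounds)
            j_hi = i
            while j_hi < b and len(_norm_ws(
                    doc.text[doc.tokens[i].start:doc.tokens[j_hi].end])) <= max_chars:
                j_hi += 1
            for j in range(j_hi, i, -1):
                start = doc.tokens[i].start
                end = doc.tokens[j - 1].end
                surface = _norm_ws(doc.text[start:end])
                ids = d.lookup(surface,
                               case_sensitive_only=not policy.case_insensitive_long)
                rtype = None
                if ids:
                    rtype = d.rtype_of(ids)
                elif surface in extra:
                    rtype = extra[surface]
                if rtype is not None:
                    if policy.go_suppression and _inside_identifier(doc.text, end):
                        continue
                    hit = (j, Mention(doc.doc_id, start, end,
                                      doc.text[start:end], rtype=rtype,
                                      source="dictionary"))
                    break
            if hit:
                i = hit[0]
                mentions.append(hit[1])
            else:
                i += 1
    return mentions


def _inside_identifier(text: str, end: int) -> bool:
    """True when the span ending at ``end`` is immediately followed by
    ``:<digit>`` — the prefix of a database identifier."""
    return end + 1 < len(text) and text[end] == ":" and text[end + 1].isdigit()


# ---------------------------------------------------------------------------
# Abbreviation detection ("Long Form (SF)")
# ---------------------------------------------------------------------------

def detect_abbreviations(doc: Document) -> list[tuple[tuple[int, int], str]]:
    """Detect parenthesised short-form definitions, Schwartz–Hearst style.

    Scans for ``( SF )`` where SF is a plausible abbreviation (2–10
    characters, at least one letter, at most two tokens), then searches the
    preceding tokens for the shortest long form whose word-initial and
    word-internal characters contain the short form's characters in order,
    with the short form's first character matching the first character of
    the first long-form word.

    Returns ``[((long_start, long_end), short_form), ...]`` in document
    order.  "two percent (2 %)" yields nothing — the candidate fails the
    letter-overlap test.
    """
    pairs: list[tuple[tuple[int, int], str]] = []
    for a, b in doc.sentences:
        toks = doc.tokens[a:b]
        for k, t in enumerate(toks):
            if t.text != "(":
                continue
            close = next((j for j in range(k + 1, min(k + 4, len(toks)))
                          if toks[j].text == ")"), None)
            if close is None or close == k + 1:
                continue
            inner = toks[k + 1:close]
            short = doc.text[inner[0].start:inner[-1].end]
            if not _plausible_short_form(short):
                continue
            span = _find_long_form(doc, toks[:k], short)
            if span is not None:
                pairs.append((span, short))
    return pairs


def _plausible_short_form(s: str) -> bool:
    s = s.strip()
    if not (2 <= len(s) <= 10):
        return False
    if len(s.split()) > 2:
        return False
    if not any(c.isalpha() for c in s):
        return False
    return s[0].isalnum()


def _find_long_form(doc: Document, prev_tokens: Sequence, short: str
                    ) -> tuple[int, int] | None:
    """Shortest token suffix before '(' that matches the short form."""
    letters = [c for c in short if c.isalnum()]
    if not letters:
        return None
    max_words = min(len(prev_tokens), min(len(letters) + 5, len(letters) * 2))
    for n_words in range(1, max_words + 1):
        cand = prev_tokens[-n_words:]
        if any(not c.text[0].isalnum() for c in cand):
            continue
        text = doc.text[cand[0].start:cand[-1].end]
        if _chars_match(text, letters, first_word_initial=True):
            return (cand[0].start, cand[-1].end)
    return None


def _chars_match(long_form: str, letters: Sequence[str],
                 first_word_initial: bool) -> bool:
    """Short-form characters must occur in order in the long form
    (case-insensitive); the first must be the long form's initial."""
    lf = long_form.lower()
    ls = [c.lower() for c in letters]
    if first_word_initial and (not lf or lf[0] != ls[0]):
        return False
    pos = 0
    for c in ls:
        found = lf.find(c, pos)
        if found < 0:
            return False
        pos = found + 1
    return True


# ---------------------------------------------------------------------------
# Ambiguity reporting
# ---------------------------------------------------------------------------

def load_word_list(path: str | Path) -> set[str]:
    """Plain one-term-per-line UTF-8 word list."""
    return {line.strip() for line in
            Path(path).read_text(encoding="utf-8").splitlines() if line.strip()}


def ambiguity_report(names: Iterable[str] | ResourceDictionary,
                     word_lists: Mapping[str, Iterable[str]],
                     case_sensitive: bool = True
                     ) -> dict[str, tuple[set[str], int]]:
    """Overlap of resource names with each supplied word list.

    Returns, per list name, the set of resource names present in the list
    and its count.  With ``case_sensitive=False`` both sides are
    lowercased before intersection (reported names keep their original
    form).
    """
    if isinstance(names, ResourceDictionary):
        names = names.all_names()
    names = set(names)
    report: dict[str, tuple[set[str], int]] = {}
    for list_name, words in word_lists.items():
        words = set(words)
        if case_sensitive:
            hit = names & words
        else:
            lowered = {w.lower() for w in words}
            hit = {n for n in names if n.lower() in lowered}
        report[list_name] = (hit, len(hit))
    return report
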