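"""Per-token features for sequence labelling of resource names.

Four feature groups, mirroring what works for name-like entities in
scientific prose:

* **orthographic** — two token-shape abstractions plus six regex-style
  boolean flags (acronym, capitalisation, digits);
* **dictionary** — a single boolean: does the token occur in (or inside a
  multi-word variant of) the resource dictionary;
* **lexical** — the token itself, its lemma and POS tag;
* **syntactic** — the alphabetically sorted, underscore-joined dependency
  relations the token participates in ("advmod_pobj"), with an explicit
  "NONE" sentinel.

Feature vectors are assembled over a fixed context window: the two tokens
before and the one token after the current token, with out-of-sentence
offsets filled by boundary sentinels so the feature space stays stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import Document, Token
from .dictionary import ResourceDictionary

FEATURE_GROUPS = ("orthographic", "dictionary", "lexical", "syntactic")

#: neighbour offsets included in each token's feature vector
DEFAULT_WINDOW = (-2, -1, 1)

_BOUNDARY = "<PAD>"
_NO_RELATION = "NONE"


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

def shape_full(token: str) -> str:
    """Character-class transliteration: capital→X, lower→x, digit→d,
    other→S.  "MySQL" → "XxXXX"."""
    if not token:
        raise FeatureError("empty token")
    out = []
    for c in token:
        if c.isupper():
            out.append("X")
        elif c.islower():
            out.append("x")
        elif c.isdigit():
            out.append("d")
        else:
            out.append("S")
    return "".join(out)


def shape_signature(token: str) -> str:
    """Fixed four-slot presence signature [capital, lower, digit, other];
    absent classes are "_".  "MySQL" → "Xx__"."""
    if not token:
        raise FeatureError("empty token")
    has_upper = any(c.isupper() for c in token)
    has_lower = any(c.islower() for c in token)
    has_digit = any(c.isdigit() for c in token)
    has_other = any(not c.isalnum() for c in token)
    return ("X" if has_upper else "_") + ("x" if has_lower else "_") + \
           ("d" if has_digit else "_") + ("S" if has_other else "_")


# ---------------------------------------------------------------------------
# Orthographic boolean flags
# ---------------------------------------------------------------------------

_ACRONYM_RE = re.compile(r"(?=(?:.*[A-Z]){2})[A-Z][A-Z0-9]+$")


def is_acronym(token: str) -> bool:
    """Two or more characters, first a capital, all characters capitals or
    digits, at least two letters.  "SCOP", "CLUSTALW" yes; "S4" no."""
    return bool(_ACRONYM_RE.match(token))


def ortho_flags(token: str) -> dict[str, bool]:
    """The six regex-extracted orthographic indicator features."""
    letters = [c for c in token if c.isalpha()]
    return {
        "isAcronym": is_acronym(token),
        "containsAllCaps": bool(letters) and all(c.isupper() for c in letters),
        "isCapitalised": bool(token) and token[0].isupper(),
        "containsCapLetter": any(c.isupper() for c in token),
        "containsDigits": any(c.isdigit() for c in token),
        "isAllDigits": bool(token) and all(c.isdigit() for c in token),
    }


# ---------------------------------------------------------------------------
# Dictionary feature
# ---------------------------------------------------------------------------

def dict_flag(token: str, d: ResourceDictionary | None) -> bool:
    """True iff the token occurs as a dictionary variant or as a
    whitespace-delimited token of a multi-word variant."""
    return bool(d) and d.contains_token(token)


# ---------------------------------------------------------------------------
# Syntactic feature
# ---------------------------------------------------------------------------

@dataclass
class DependencyGraph:
    """Per-token dependency relations, as (relation label, role) pairs with
    role in {"governor", "dependant"}.  May be empty: parsers are pluggable
    providers and their absence degrades to the "NONE" sentinel."""

    relations: dict[int, list[tuple[str, str]]] = field(default_factory=dict)

    def for_token(self, index: int) -> list[tuple[str, str]]:
        return self.relations.get(index, [])


def syntactic_feature(token_index: int, graph: DependencyGraph | None) -> str:
    """Alphabetically sorted, underscore-joined relation labels for the
    token ({pobj, advmod} → "advmod_pobj"); "NONE" when the token has no
    relations or no parse is available."""
    if graph is None:
        return _NO_RELATION
    labels = sorted({rel.lower() for rel, _role in graph.for_token(token_index)})
    return "_".join(labels) if labels else _NO_RELATION


_VERBISH = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"}


def heuristic_dependencies(sent_tokens: Sequence[Token]) -> DependencyGraph:
    """A light, deterministic relation provider for synthetic text: nouns
    left of a verb get "nsubj", nouns right of a preposition get "pobj",
    adverbs get "advmod".  Stands in only so the syntactic feature group is
    exercised end to end; any real parser can replace it."""
    rel: dict[int, list[tuple[str, str]]] = {}
    for k, t in enumerate(sent_tokens):
        if t.pos.startswith("NN"):
            nxt = sent_tokens[k + 1] if k + 1 < len(sent_tokens) else None
            prev = sent_tokens[k - 1] if k > 0 else None
            if nxt is not None and nxt.pos in _VERBISH:
                rel.setdefault(k, []).append(("nsubj", "dependant"))
            if prev is not None and prev.pos == "IN":
                rel.setdefault(k, []).append(("pobj", "dependant"))
        elif t.pos == "RB":
            rel.setdefault(k, []).append(("advmod", "dependant"))
    return DependencyGraph(rel)


# ---------------------------------------------------------------------------
# Window assembly
# ---------------------------------------------------------------------------

def token_features(token: Token, d: ResourceDictionary | None,
                   sent_offset_index: int,
                   graph: DependencyGraph | None,
                   groups: Sequence[str]) -> dict[str, str]:
    """Feature-name → value map for one token (no window)."""
    f: dict[str, str] = {}
    if "orthographic" in groups:
        f["shape"] = shape_full(token.text)
        f["sig"] = shape_signature(token.text)
        for name, val in ortho_flags(token.text).items():
            f[name] = str(val)
    if "dictionary" in groups:
        f["inDict"] = str(dict_flag(token.text, d))
    if "lexical" in groups:
        f["w"] = token.text
        f["lemma"] = token.lemma
        f["pos"] = token.pos
    if "syntactic" in groups:
        f["dep"] = syntactic_feature(sent_offset_index, graph)
    return f


def build_feature_window(sent_tokens: Sequence[Token], i: int,
                         d: ResourceDictionary | None = None,
                         graph: DependencyGraph | None = None,
                         groups: Sequence[str] = FEATURE_GROUPS,
                         window: Sequence[int] = DEFAULT_WINDOW
                         ) -> dict[str, str]:
    """Feature vector for position ``i`` of a sentence: the token's own
    feature groups plus neighbour copies at the window offsets (default
    −2, −1, +1).  Offsets falling outside the sentence contribute explicit
    boundary-sentinel values, keeping the feature space identical at
    sentence edges."""
    if not (0 <= i < len(sent_tokens)):
        raise FeatureError(f"position {i} outside sentence of {len(sent_tokens)}")
    vec = dict(token_features(sent_tokens[i], d, i, graph, groups))
    for off in window:
        j = i + off
        tag = f"{off:+d}"
        if 0 <= j < len(sent_tokens):
            for name, val in token_features(sent_tokens[j], d, j, graph,
                                            groups).items():
                vec[f"{tag}:{name}"] = val
        else:
            vec[f"{tag}:w"] = _BOUNDARY
    return vec


def featurize_document(doc: Document, d: ResourceDictionary | None = None,
                       groups: Sequence[str] = FEATURE_GROUPS,
                       window: Sequence[int] = DEFAULT_WINDOW,
                       parser=heuristic_dependencies
                       ) -> list[list[dict[str, str]]]:
    """Feature vectors per sentence, aligned to the document's tokens."""
    unknown = set(groups) - set(FEATURE_GROUPS)
    if unknown:
        raise FeatureError(f"unknown feature group(s) {sorted(unknown)}")
    out: list[list[dict[str, str]]] = []
    for si in range(len(doc.sentences)):
        sent = doc.sentence_tokens(si)
        graph = parser(sent) if (parser is not None and "syntactic" in groups) else None
        out.append([build_feature_window(sent, i, d, graph, groups, window)
                    for i in range(len(sent))])
    return out
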