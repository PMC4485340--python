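"""Two-pass post-processing of tagger output.

A large share of sequence-tagger false negatives are repeats: a resource
name recognised at least once in a document but missed elsewhere.  The
remedy is transductive: the first pass collects every tagging decision
over the corpus being tagged; the second pass promotes a still-O token to
part of a mention only when all three conditions hold —

1. across the tagged corpus, its exact surface string was labelled B or I
   strictly more often than it was labelled O;
2. it is in the resource dictionary, or it is an acronym of at least two
   characters containing no digits;
3. it is not on the blacklist of notorious false-positive surfaces
   (by default: "analysis", "genomes", "cycle" and "cell").

The pass only ever adds labels; existing B/I labels are never removed, so
token-level recall cannot decrease.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import Document, LabelSequence
from .dictionary import ResourceDictionary

#: surfaces never promoted in the second pass (compared case-insensitively)
DEFAULT_BLACKLIST = ("analysis", "genomes", "cycle", "cell")


class PostprocessError(ValueError):
    pass


@dataclass
class TokenVotes:
    """First-pass tagging votes per exact (case-sensitive) token surface."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def labelled(self, surface: str) -> int:
        return self.counts.get(surface, (0, 0))[0]

    def unlabelled(self, surface: str) -> int:
        return self.counts.get(surface, (0, 0))[1]

    def majority_labelled(self, surface: str) -> bool:
        """Strict majority: ties are rejected ("more often than it was not")."""
        lab, unlab = self.counts.get(surface, (0, 0))
        return lab > unlab


def collect_token_votes(tagged: Sequence[tuple[Document, LabelSequence]]
                        ) -> TokenVotes:
    """Count, for every token surface in the tagged corpus, how often it
    was labelled (B or I) versus left O in the first pass."""
    counts: dict[str, list[int]] = {}
    for doc, seq in tagged:
        if len(seq.labels) != len(doc.tokens):
            raise PostprocessError(f"{doc.doc_id}: label/token length mismatch")
        for tok, lab in zip(doc.tokens, seq.labels):
            c = counts.setdefault(tok.text, [0, 0])
            c[0 if lab in ("B", "I") else 1] += 1
    return TokenVotes({k: (v[0], v[1]) for k, v in counts.items()})


_ACRONYM_NO_DIGITS = re.compile(r"[A-Z]{2,}$")


def acronym_eligible(token: str) -> bool:
    """Second-pass acronym condition: all capital letters, no digits, at
    least two characters.  Stricter than the feature-level acronym flag,
    which admits digits."""
    return bool(_ACRONYM_NO_DIGITS.match(token))


def second_pass_relabel(tagged: Sequence[tuple[Document, LabelSequence]],
                        votes: TokenVotes,
                        d: ResourceDictionary | None,
                        blacklist: Sequence[str] = DEFAULT_BLACKLIST
                        ) -> list[tuple[Document, LabelSequence]]:
    """Promote eligible O tokens to mention labels.

    Votes must come from the same corpus (every token surface present);
    a surface missing from the votes raises :class:`PostprocessError`.
    Adjacent promoted tokens merge into one mention: the first promoted
    token of a run becomes B, the following ones I.  Given fixed votes the
    operation is idempotent.
    """
    bl = {b.lower() for b in blacklist}
    out: list[tuple[Document, LabelSequence]] = []
    for doc, seq in tagged:
        if len(seq.labels) != len(doc.tokens):
            raise PostprocessError(f"{doc.doc_id}: label/token length mismatch")
        labels = list(seq.labels)
        promoted = [False] * len(labels)
        for k, (tok, lab) in enumerate(zip(doc.tokens, labels)):
            if lab != "O":
                continue
            surf = tok.text
            if surf not in votes.counts:
                raise PostprocessError(
                    f"{doc.doc_id}: token {surf!r} absent from first-pass votes "
                    "(votes/corpus mismatch)")
            if surf.lower() in bl:
                continue
            if not votes.majority_labelled(surf):
                continue
            if not ((d is not None and d.contains_token(surf))
                    or acronym_eligible(surf)):
                continue
            promoted[k] = True
        for k in range(len(labels)):
            if promoted[k]:
                labels[k] = "I" if (k > 0 and promoted[k - 1]) else "B"
        out.append((doc, LabelSequence(doc_id=doc.doc_id, labels=labels)))
    return out


def apply(tagged: Sequence[tuple[Document, LabelSequence]],
          d: ResourceDictionary | None,
          blacklist: Sequence[str] = DEFAULT_BLACKLIST,
          per_document: bool = False
          ) -> list[tuple[Document, LabelSequence]]:
    """Run both passes over a tagged corpus.

    By default votes are pooled over the whole corpus being tagged
    (transductive); ``per_document=True`` restricts vote collection to each
    document separately.
    """
    if not per_document:
        votes = collect_token_votes(tagged)
        return second_pass_relabel(tagged, votes, d, blacklist)
    out: list[tuple[Document, LabelSequence]] = []
    for pair in tagged:
        votes = collect_token_votes([pair])
        out.extend(second_pass_relabel([pair], votes, d, blacklist))
    return out
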