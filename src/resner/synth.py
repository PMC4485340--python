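"""Seeded synthetic corpora for end-to-end testing without downloads.

Real full-text corpora of database/software mentions exhibit a handful of
statistical phenomena that drive recogniser behaviour: mentions repeat
within a document; many surface forms occur exactly once in the corpus;
names appear as acronym or case variants; a share of names are newly
introduced resources absent from any dictionary; some names collide with
common English words used innocently elsewhere; and mentions often sit in
clue-bearing contexts (head terms, enumerations, versions, citations,
comparisons, "Name: description" titles).  The generator emulates exactly
these phenomena from parameterised templates, emitting documents and gold
annotations in the same in-memory and on-disk formats as real corpora.

Everything is deterministic given the seed: the same configuration
produces byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import (DATABASE, SOFTWARE, Document, Mention, make_document)
from .dictionary import DictionaryEntry, ResourceDictionary


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Toy dictionary
# ---------------------------------------------------------------------------

_SYL_A = ["Gen", "Sim", "Bio", "Seq", "Map", "Net", "Prot", "Chem", "Path",
          "Tax", "Var", "Struct", "Align", "Phylo", "Meta", "Omic"]
_SYL_B = ["Miner", "Finder", "Scan", "Base", "Bank", "Works", "Suite", "Lab",
          "Press", "Viewer", "Forge", "Hub", "Mark", "Fold", "Link", "Craft"]

#: canonical names that are also common English words — the ambiguity the
#: recogniser has to survive
AMBIGUOUS_NAMES = ("analysis", "cycle", "graph", "network")


def make_toy_dictionary(n_names: int, seed: int = 0,
                        include_ambiguous: bool = True) -> ResourceDictionary:
    """Generate a deterministic resource dictionary of ``n_names`` entries.

    Names are drawn from three shape templates seen in real inventories:
    CamelCase compounds ("SimFinder"), all-caps acronyms ("BProt"-style
    "BPRT"), and compounds with a trailing digit ("GenScan2"); a quarter of
    the entries are two-word names whose initials form an acronym variant.
    With ``include_ambiguous`` four common-English-word entries are
    appended (not counted in ``n_names``).
    """
    if n_names < 1:
        raise SynthError("n_names must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[DictionaryEntry] = []
    seen: set[str] = set()

    def camel() -> str:
        return str(rng.choice(_SYL_A)) + str(rng.choice(_SYL_B))

    while len(entries) < n_names:
        shape = rng.integers(0, 4)
        variants: set[str] = set()
        if shape == 0:
            name = camel()
        elif shape == 1:
            n = int(rng.integers(3, 7))
            name = "".join(chr(65 + int(c)) for c in rng.integers(0, 26, n))
        elif shape == 2:
            name = camel() + str(int(rng.integers(2, 10)))
        else:
            w1, w2 = camel(), str(rng.choice(_SYL_B)) + "er"
            name = f"{w1} {w2}"
            variants.add((w1[0] + w2[0]).upper())  # acronym variant
        if name in seen or name in _RESERVED:
            continue
        seen.add(name)
        rtype = ("DB", "SW", "PK")[len(entries) % 3]
        entries.append(DictionaryEntry(canonical=name, rtype=rtype,
                                       source="synthetic", variants=variants))
    if include_ambiguous:
        for k, name in enumerate(AMBIGUOUS_NAMES):
            entries.append(DictionaryEntry(canonical=name,
                                           rtype=("SW", "PK")[k % 2],
                                           source="synthetic-ambiguous"))
    return ResourceDictionary(entries)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Knobs of the generator; rates are probabilities in [0, 1].

    Defaults mirror a development-scale full-text corpus: 60 documents
    averaging ~40 mentions each, about half of all mention instances being
    within-document repeats, roughly a quarter of mention types realised
    as a non-canonical variant, a quarter of types being novel
    (out-of-dictionary) resources, a small ambiguous-name share, and close
    to a third of mention sentences carrying an explicit textual clue.
    """

    n_docs: int = 60
    mentions_per_doc: float = 40.0
    # a development-scale corpus averages ~8 unique names per ~40 mentions
    # per document, i.e. roughly 4 in 5 mention instances repeat a name
    # already used in the same document
    repetition_rate: float = 0.8
    novel_name_rate: float = 0.25
    ambiguity_rate: float = 0.05
    variant_rate: float = 0.24
    clue_context_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise SynthError("n_docs must be >= 1")
        for name in ("repetition_rate", "novel_name_rate", "ambiguity_rate",
                     "variant_rate", "clue_context_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Sentence templates ({} marks a name slot)
# ---------------------------------------------------------------------------

_PLAIN = [
    "We used {} to process the data.",
    "All sequences were aligned with {}.",
    "The output of {} was inspected manually.",
    "Annotations were retrieved from {}.",
    "{} was applied to the filtered set.",
    "Records were exported from {} for curation.",
    # low-signal contexts: nothing in the sentence marks the slot as a
    # resource, so recognition must come from the name itself
    "{} results were consistent with the reference.",
    "{} failed on two of the inputs.",
    "The comparison included {} as well.",
    "{} produced the expected counts.",
]

#: unannotated noun phrases filled into the same plain templates, so that
#: sentence context alone cannot identify a mention
_PLAIN_DISTRACTORS = ["the pipeline", "the workflow", "the cluster",
                      "the protocol", "the reference set", "the script",
                      "the procedure", "manual curation"]

#: non-resource acronyms and proper nouns that defeat purely orthographic
#: decisions, as in real prose (methods sections name machines, places,
#: molecules)
_ACRO_DISTRACTORS = ["DNA", "RNA", "PCR", "CPU", "RAM", "USA", "HIV", "ATP"]
_PROPER_DISTRACTORS = ["Germany", "London", "Europe", "Monday", "Atlantic",
                       "Spring", "Tuesday", "Manchester"]

#: surfaces the toy dictionary must never generate as resource names
_RESERVED = set(_ACRO_DISTRACTORS) | set(_PROPER_DISTRACTORS)

# clue templates exercise each detector category
_CLUE_ONE = [
    "The {} software was used throughout.",
    "We ran the stochastic simulator {} on each model.",
    "The {} database stores the curated records.",
    "We used {} version 1.83 for the alignment.",
    "Results were generated using {} v2.",
    "{} [12] was downloaded from the project page.",
]
_CLUE_TWO = [
    "{} did better than {} on the benchmark.",
    "{} was much slower than {} in our hands.",
    "Like {}, {} dynamically generates the output.",
]
_CLUE_THREE = [
    "We compared tools such as {}, {}, and {}.",
    "The following programs were tested: {}, {}, and {}.",
]

_FILLER = [
    "The experiments were repeated three times.",
    "Samples were collected from the full cohort.",
    "Results are shown in the supplementary material.",
    "The parameters were estimated from the training data.",
    "Each run completed within a few minutes.",
    "The protocol followed the published guidelines.",
]

#: terse frames used both for repeat mentions and for non-resource
#: acronyms — context alone cannot resolve the slot
_TERSE = [
    "The {} step was repeated twice.",
    "The {} run finished overnight.",
    "{} output was archived for review.",
]

#: distractor-bearing filler: {} is filled with an unannotated acronym or
#: proper noun, never a resource
_ACRO_FILLER = _TERSE
_PROPER_FILLER = [
    "Samples were shipped from {} in batches.",
    "The {} cohort was recruited separately.",
    "Reviewers from {} examined the release.",
]

#: filler that uses ambiguous common words in their ordinary reading
_AMBIG_FILLER = [
    "The analysis of the expression data took several hours.",
    "Each cycle of the procedure was logged.",
    "The resulting graph summarises the trend.",
    "The regulatory network remains poorly understood.",
]

_TITLE_TEMPLATE = "{}: a simulator for expression data"


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

class _NamePool:
    """Draws mention types per the configured novelty/ambiguity/variant
    mix, tracking which surfaces are dictionary-resolvable."""

    def __init__(self, cfg: SynthConfig, d: ResourceDictionary,
                 rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.regular = [e for e in d.entries
                        if e.canonical not in AMBIGUOUS_NAMES]
        self.ambiguous = [e for e in d.entries
                          if e.canonical in AMBIGUOUS_NAMES]
        self.dict_surfaces = set(d.unique_variants())
        self.novel_seen: set[str] = set()

    def distractor_acronym(self) -> str:
        """A non-resource acronym (molecule, machine, consortium...):
        drawn from an open class so that surface memorisation cannot
        substitute for context."""
        if self.rng.random() < 0.4:
            return _ACRO_DISTRACTORS[
                int(self.rng.integers(0, len(_ACRO_DISTRACTORS)))]
        while True:
            n = int(self.rng.integers(3, 6))
            name = "".join(chr(65 + int(c))
                           for c in self.rng.integers(0, 26, n))
            if name not in self.dict_surfaces and name not in self.novel_seen:
                return name

    def _novel_name(self) -> str:
        # newly introduced resources: mixed-case compounds or, often,
        # acronyms defined nowhere (the kind only context can reveal)
        while True:
            if self.rng.random() < 0.4:
                n = int(self.rng.integers(3, 7))
                name = "".join(chr(65 + int(c))
                               for c in self.rng.integers(0, 26, n))
            else:
                a = str(self.rng.choice(_SYL_B))
                b = str(self.rng.choice(_SYL_A))
                name = ("x" if self.rng.random() < 0.3 else "") + b + a
            if name not in self.dict_surfaces and name not in self.novel_seen \
                    and name not in _RESERVED:
                self.novel_seen.add(name)
                return name

    def draw_type(self) -> tuple[str, str, bool]:
        """Return (surface, rtype, is_novel) for a fresh mention type."""
        u = self.rng.random()
        if u < self.cfg.novel_name_rate:
            return self._novel_name(), SOFTWARE, True
        if self.ambiguous and u < self.cfg.novel_name_rate + self.cfg.ambiguity_rate:
            e = self.ambiguous[int(self.rng.integers(0, len(self.ambiguous)))]
            return e.canonical, SOFTWARE, False
        e = self.regular[int(self.rng.integers(0, len(self.regular)))]
        surface = e.canonical
        alt = sorted(e.variants - {e.canonical})
        if alt and self.rng.random() < self.cfg.variant_rate:
            surface = alt[int(self.rng.integers(0, len(alt)))]
        rtype = DATABASE if e.rtype == "DB" else SOFTWARE
        return surface, rtype, False


class _DocBuilder:
    """Accumulates sentences while tracking gold-mention offsets."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.mentions: list[Mention] = []

    def add(self, template: str, names: Sequence[tuple[str, str]] = ()) -> None:
        pieces = template.split("{}")
        if len(pieces) != len(names) + 1:
            raise SynthError("template slot count does not match names")
        if self.parts:  # single space between sentences
            self.parts.append(" ")
            self.length += 1
        text = ""
        for k, (surface, rtype) in enumerate(names):
            text += pieces[k]
            start = self.length + len(text)
            text += surface
            self.mentions.append(Mention(self.doc_id, start,
                                         start + len(surface), surface,
                                         rtype=rtype, source="gold"))
        text += pieces[-1]
        self.parts.append(text)
        self.length += len(text)

    def build(self, title: str = "",
              preserve_identifiers: bool = True) -> tuple[Document, list[Mention]]:
        text = "".join(self.parts)
        doc = make_document(self.doc_id, text, title=title,
                            preserve_identifiers=preserve_identifiers)
        for m in self.mentions:
            assert doc.text[m.start:m.end] == m.surface
        return doc, sorted(self.mentions, key=lambda m: m.start)


def generate_corpus(cfg: SynthConfig, d: ResourceDictionary
                    ) -> list[tuple[Document, list[Mention]]]:
    """Generate an annotated corpus under ``cfg`` against dictionary ``d``.

    Every document is built from mention-bearing sentences (plain or
    clue-templated), neutral filler, and — when ambiguity is configured —
    filler using ambiguous common words in their ordinary, unannotated
    reading.  Gold mentions satisfy all span invariants and align with
    token boundaries by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _NamePool(cfg, d, rng)
    corpus: list[tuple[Document, list[Mention]]] = []
    for di in range(cfg.n_docs):
        doc_id = f"synth{di:04d}"
        b = _DocBuilder(doc_id)
        n_mentions = max(1, int(rng.poisson(cfg.mentions_per_doc)))
        doc_types: list[tuple[str, str]] = []  # (surface, rtype) used here

        title = ""
        if rng.random() < cfg.clue_context_rate:
            surface, rtype, _ = pool.draw_type()
            title = _TITLE_TEMPLATE.format(surface)
            doc_types.append((surface, rtype))

        instances: list[tuple[str, str]] = []
        repeats: list[bool] = []
        while len(instances) < n_mentions:
            if doc_types and rng.random() < cfg.repetition_rate:
                surface, rtype = doc_types[int(rng.integers(0, len(doc_types)))]
                repeats.append(True)
            else:
                surface, rtype, _ = pool.draw_type()
                doc_types.append((surface, rtype))
                repeats.append(False)
            instances.append((surface, rtype))

        i = 0
        while i < len(instances):
            # a repeat mention often recurs in terse, uninformative prose
            # ("The X step was repeated twice.") — the same frames that
            # elsewhere hold non-resource acronyms, which is where taggers
            # miss a name they already recognised once
            if repeats[i] and rng.random() < 0.4:
                b.add(_TERSE[int(rng.integers(0, len(_TERSE)))],
                      instances[i:i + 1])
                i += 1
            elif rng.random() < cfg.clue_context_rate:
                room = len(instances) - i
                if room >= 3 and rng.random() < 0.3:
                    b.add(_CLUE_THREE[int(rng.integers(0, len(_CLUE_THREE)))],
                          instances[i:i + 3])
                    i += 3
                elif room >= 2 and rng.random() < 0.4:
                    b.add(_CLUE_TWO[int(rng.integers(0, len(_CLUE_TWO)))],
                          instances[i:i + 2])
                    i += 2
                else:
                    b.add(_CLUE_ONE[int(rng.integers(0, len(_CLUE_ONE)))],
                          instances[i:i + 1])
                    i += 1
            else:
                b.add(_PLAIN[int(rng.integers(0, len(_PLAIN)))],
                      instances[i:i + 1])
                i += 1
            u = rng.random()
            if u < 0.10:  # a mention-style context holding a non-mention
                t = _PLAIN[int(rng.integers(0, len(_PLAIN)))]
                w = _PLAIN_DISTRACTORS[int(rng.integers(0, len(_PLAIN_DISTRACTORS)))]
                b.add(t.format(w))
            elif u < 0.34:
                t = _ACRO_FILLER[int(rng.integers(0, len(_ACRO_FILLER)))]
                b.add(t.format(pool.distractor_acronym()))
            elif u < 0.42:
                t = _PROPER_FILLER[int(rng.integers(0, len(_PROPER_FILLER)))]
                w = _PROPER_DISTRACTORS[int(rng.integers(0, len(_PROPER_DISTRACTORS)))]
                b.add(t.format(w))
            elif u < 0.60:
                b.add(_FILLER[int(rng.integers(0, len(_FILLER)))])
            if cfg.ambiguity_rate > 0 and rng.random() < cfg.ambiguity_rate:
                b.add(_AMBIG_FILLER[int(rng.integers(0, len(_AMBIG_FILLER)))])
        corpus.append(b.build(title=title))
    return corpus


# ---------------------------------------------------------------------------
# Orthography-separable corpus
# ---------------------------------------------------------------------------

_NEUTRAL = [
    "the team evaluated {} carefully.",
    "we then considered {} in detail.",
    "results for {} were recorded.",
    "a report on {} followed.",
    "they discussed {} at length.",
]

#: syllables for plain capitalised distractor pseudo-words ("Monvale"):
#: shape Xxxx... with no internal capital or digit, unlike resource names
_DIST_SYL = ["mon", "ger", "lon", "eur", "atl", "spri", "win", "pac", "tor",
             "vale", "den", "mar", "bri", "hol", "sax", "nor"]


def generate_ortho_corpus(n_docs: int, sentences_per_doc: int = 20,
                          seed: int = 0
                          ) -> list[tuple[Document, list[Mention]]]:
    """A corpus where resource names are separable *only* by orthography.

    Every sentence uses the same neutral templates; the slot holds either a
    never-repeated resource name of distinctive shape (mixed-case compound,
    acronym, or digit-bearing) or a never-repeated plain capitalised
    pseudo-word.  Both readings share POS tag and sentence context, and
    neither vocabulary recurs, so token identity cannot be memorised across
    folds — the orthographic feature group carries all the separating
    signal.
    """
    if n_docs < 1:
        raise SynthError("n_docs must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[tuple[Document, list[Mention]]] = []
    used: set[str] = set()

    def fresh_distractor() -> str:
        while True:
            parts = [str(rng.choice(_DIST_SYL))
                     for _ in range(int(rng.integers(2, 4)))]
            w = "".join(parts).capitalize()
            if w not in used:
                used.add(w)
                return w

    def fresh_name() -> str:
        # acronyms and digit-bearing compounds: their orthographic flags
        # (isAcronym, containsDigits) are stable separating features,
        # unlike full shape strings, which are length-specific
        while True:
            if rng.random() < 0.5:
                n = int(rng.integers(4, 8))
                name = "".join(chr(65 + int(c)) for c in rng.integers(0, 26, n))
            else:
                name = str(rng.choice(_SYL_A)) + str(rng.choice(_SYL_B)) \
                    + str(int(rng.integers(2, 100)))
            if name not in used and name not in _RESERVED:
                used.add(name)
                return name

    for di in range(n_docs):
        b = _DocBuilder(f"ortho{di:04d}")
        for _ in range(sentences_per_doc):
            t = _NEUTRAL[int(rng.integers(0, len(_NEUTRAL)))]
            if rng.random() < 0.5:
                b.add(t, [(fresh_name(), SOFTWARE)])
            else:
                b.add(t.format(fresh_distractor()))
        corpus.append(b.build())
    return corpus
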