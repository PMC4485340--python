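# Methods

This note documents the models, rules and numerical choices behind
`resner`, what the synthetic data does and does not emulate, and the design
decisions taken where more than one reasonable option existed.

## Text model and preprocessing

A `Document` is raw text plus character-offset tokens (0-based, half-open
spans) carrying a Penn-style POS tag, a lemma and a sentence index.
Mentions are character spans; `mentions_to_bio` / `bio_to_mentions` convert
between spans and per-token B/I/O labels and are inverses on token-aligned,
non-overlapping input. A mention boundary falling inside a token is
snapped *outward* to the covering tokens with a logged warning — widening
keeps the mention countable for recall instead of silently dropping it.

The tokeniser, sentence splitter and POS tagger are rule-based providers
written for this package; the module contract is only that tokens satisfy
their invariants (exact slices, sorted, non-overlapping) and that the same
text always yields the same annotations, so any external pipeline honouring
that contract can be substituted. Two deliberate choices:

- **Identifier-preserving tokenisation** (default on): accession-style
  patterns `prefix:digits` such as `GO:0007089` stay one token. Database
  identifiers are not resource names; splitting them exposes the prefix
  (`GO`) to spurious dictionary matches. The option can be turned off to
  reproduce that failure mode.
- The POS tagger is deliberately small (closed-class word lists, suffix
  rules, orthographic cues mapping name-like tokens to `NNP`). It is
  adequate for the synthetic corpora and for POS-pattern analytics; on real
  text a full tagger should be plugged in.

Dependency parses are an optional input (`DependencyGraph`); without a
parser the syntactic feature degrades to its `NONE` sentinel. A small
heuristic relation provider (subjects, prepositional objects, adverbial
modifiers) is included so the syntactic feature group is exercised end to
end. Relations attach per token; no propagation from phrase heads is
attempted.

## Dictionary matching

Matching is **leftmost-longest on token boundaries**: at each token the
longest candidate span whose whitespace-normalised surface equals a
dictionary variant wins, and scanning resumes after it. Candidate length
is bounded by the longest variant in characters (not word count — a
one-word variant like `t2prhd` can span several tokens).

- **Case policy.** Variants of length ≤ 4 or in all capitals match only
  case-sensitively; longer mixed-case variants also match
  case-insensitively. Case-folding short names multiplies collisions with
  common English words by an order of magnitude, so short names stay
  strict.
- **Identifier suppression** (default on): a candidate immediately
  followed by `:` + digit is rejected.
- **Abbreviation expansion** (default on): parenthesised short forms are
  paired with a preceding long form by an in-order character-subsequence
  test (the short form's first character must start the long form; "two
  percent (2 %)" fails the test). Short forms whose long form is a
  dictionary variant become document-local variants for a second matching
  pass.
- Duplicate variants across entries are kept and flagged: a variant
  resolving to entries of different types yields an `UNSPECIFIED` mention
  type. Variant de-duplication for counting purposes is exact string
  equality after whitespace normalisation only.

## Sequence tagger

The tagger is a **linear-chain averaged structured perceptron** decoded
with Viterbi over the labels {O, B, I}: first-order transition weights plus
per-label weights on `feature=value` strings. The averaged perceptron was
chosen as the learner behind the module's train/tag contract because it is
deterministic, dependency-free, fast at this problem size, and a standard
strong baseline for linear sequence labelling; the module surface is
learner-agnostic, so a CRF or any other linear-chain backend can replace it
without touching callers.

Features per token: the two shape abstractions (full character-class
transliteration; four-slot presence signature), six boolean orthographic
flags, the dictionary membership bit (token equals a variant or a token of
a multi-word variant), token/lemma/POS, and the sorted dependency-relation
string. Neighbour copies at offsets −2, −1, +1 are included; positions
outside the sentence contribute an explicit `<PAD>` value so the feature
space is identical at sentence edges. The acronym flag used in features
(`isAcronym`: ≥ 2 characters, all capitals or digits, at least two
letters) is intentionally different from the post-processing acronym
condition, which excludes digits.

Training defaults: 8 epochs, per-epoch shuffling driven by a single integer
seed, lazy-averaged weights. Weights, transitions and the full
configuration (feature groups, window, epochs, seed) persist to a model
directory; load-then-tag is byte-identical to tag-before-save. Training
raises on an empty or all-O corpus — there is nothing learnable. Decoded
sequences are repaired per sentence (`I` after `O` becomes `B`); repair is
idempotent.

## Two-pass post-processing

Transductive relabelling over the corpus being tagged. Pass 1 counts, per
exact (case-sensitive) token surface, how often it was labelled B/I versus
O. Pass 2 promotes an O token iff:

1. labelled count **strictly** exceeds unlabelled count (ties reject);
2. the token is in the dictionary, **or** is an all-capital, digit-free
   token of ≥ 2 characters;
3. its lowercased surface is not blacklisted
   (`analysis`, `genomes`, `cycle`, `cell` by default; configurable).

Existing labels are never removed, so token-level recall is monotonically
non-decreasing — the trade-off is possible precision loss, bounded by the
three gates. Adjacent promoted tokens merge into one mention (first B,
rest I); which label promoted tokens receive is this package's choice.
Votes default to the whole corpus being tagged; a per-document mode
exists but is off. Vote instances are counted per token occurrence, not
per mention.

## Evaluation

- **Strict** = exact offset equality; **lenient** = any character overlap.
  Both are one-to-one matchings (greedy in gold order, largest overlap
  preferred), so a single long prediction cannot match several gold
  mentions; the converse dominance (lenient ≥ strict on every score) is
  property-tested. Evaluation is untyped by default (a typed mode exists):
  database/software labels are carried on mentions but systems are scored
  on spans.
- **Cross-validation** is document-level: seeded shuffle + round-robin, so
  fold sizes differ by ≤ 1. The dictionary baseline is evaluated on each
  held-out fold only; the tagger trains on the other k−1 folds, tags the
  held-out fold, and post-processing (when enabled) pools votes over that
  held-out fold — the corpus actually being tagged. Summaries report
  per-fold min/max/mean plus the micro-average from pooled TP/FP/FN; the
  two differ exactly when folds are unbalanced, which is asserted on
  constructed fixtures.
- **Ablation** re-runs cross-validation once per dropped feature group
  with a shared fold assignment and seed, post-processing disabled so the
  dictionary-dependent second pass cannot mask feature contributions.
- **IAA** reuses the evaluator with one annotator as gold; since the
  measure is asymmetric, both directions are reported.
- Scores are percentages reported to 1 decimal place throughout.

## Analytics

`corpus_summary` accepts either full documents or bare surface lists, so
corpus statistics can be recomputed from published totals as well as from
loaded corpora. "Unique mentions" are distinct exact surfaces
(case-sensitive). Stem frequencies use an in-package implementation of the
classic Porter algorithm (steps 1–5; verified against the published
reference pairs), ranked with an alphabetical tie-break. POS-pattern
profiles count unique (surface, pattern) pairs — one surface tagged two
ways contributes two patterns. Variability is unique variants over
resources (2 d.p.); at corpus level the grouping of surfaces into resources
is an input mapping, since it requires background knowledge.

## Clue detectors

All detectors are pure functions of a sentence (or title). Candidate
anchoring uses a *name-shaped* filter — runs of ≤ 4 tokens that are
capitalised, all-caps, mixed-case or letter+digit composites, excluding
capitalised function words; a single lowercase one-letter token is admitted
mid-run ("i Linker"). Specific guards, each motivated by a known
false-positive mode: title candidates containing "method(s)"/"algorithm(s)"
are rejected; bare version numbers followed by a unit token (GHz, MB, …)
are not version clues; citation/URL candidates must pass the name-shape
filter ("principle [14, 15]" is rejected); explicit `v`/`version` markers
license a lowercase candidate ("using dot v1.10") that the shape filter
alone would drop. The clue–mention co-occurrence statistic reports, per
regex, the fraction of clue sentences containing a gold mention and the
reverse; a regex matching nothing is flagged rather than scored.

## Synthetic corpora

The generator emulates the statistical phenomena that drive recogniser
behaviour in real annotated full text: within-document repetition of
mentions, acronym/case variants, lexically ambiguous names used both as
mentions and as plain words, novel out-of-dictionary names, clue-bearing
contexts, and distractors (non-resource acronyms such as DNA/PCR, proper
nouns, and terse frames shared between mentions and non-mentions so that
neither context nor orthography alone is sufficient). Default rates:
60 documents, mean 40 mentions/document; repetition 0.8 (a development-
scale corpus averages ~8 unique names per ~40 mentions per document);
variant rate 0.24 (about a quarter of unique corpus names are variants of
others); novel-name rate 0.25, ambiguity rate 0.05 and clue-context rate
0.3, chosen once as realistic for literature introducing new tools.
Everything is driven by one NumPy generator seed; identical configurations
produce byte-identical corpora.

A second construction, `generate_ortho_corpus`, isolates the orthographic
feature group: never-repeating resource names (acronyms and digit-bearing
compounds, whose separating features are stable booleans) and
never-repeating plain capitalised pseudo-words share identical neutral
templates and POS tags, so shape is the only separating signal.

What the generator does **not** emulate: real discourse and topical
coherence, citation structure, section layout, misspellings, and the long
tail of real name-formation patterns. Tests passing on synthetic corpora
therefore demonstrate that the machinery behaves as designed under the
stated statistical structure — not that any particular score would be
attained on real annotated articles, which additionally require a full POS
tagger and parser and a curated dictionary.

## Problem sizes and determinism

The test suite and the reproduction script run seconds-scale problems
chosen as the package's own study conditions: cross-validation and the
post-processing experiment use 20–25 documents at ~15 mentions/document
with 3 training epochs (the post-processing gain is measured by training
on one corpus, tagging another, and pooling token counts over four
independent replicates — the gain is structurally non-negative, and
pooling makes the strict-positive direction stable across seeds); the
ablation uses 16 shape-separable documents at 5 epochs. All randomness in
any run descends from one integer seed; reports, corpora and model
artifacts are byte-reproducible given seed and configuration.

## Known limitations

- The rule-based POS tagger and heuristic dependency provider are adequate
  for synthetic text and analytics, not for production tagging of real
  articles.
- The perceptron gives no probabilities; confidence-based thresholding is
  out of scope.
- Lenient matching's one-to-one greedy pairing is one of several defensible
  definitions of "offsets overlap"; it is fixed and documented here.
- Clue detectors are precision-oriented rules with hand-chosen word lists;
  combining them into a weighted voter is future work, and their detected
  candidates are not fed back into training.
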