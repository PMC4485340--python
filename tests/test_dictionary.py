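"""Dictionary building, longest-match tagging, abbreviations, ambiguity."""

import pytest
from hypothesis import given, settings, strategies as st

from resner import dictionary as dc
from resner import make_document
from resner.dictionary import (DictionaryError, MatchPolicy, ResourceDictionary,
                               ambiguity_report, detect_abbreviations,
                               load_dictionary, match)
from resner.synth import SynthConfig, generate_corpus, make_toy_dictionary
from resner.evaluation import compare_mentions


class TestLoad:
    def test_pipe_row(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("UniProt|DB|nar|UniProt|Uniprot\n")
        d = load_dictionary(p)
        assert len(d.entries) == 1
        assert d.entries[0].variants == {"UniProt", "Uniprot"}

    def test_tab_row_with_pipe_variants(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Gene Ontology\tDB\tnar\tGene Ontology|GO\n")
        d = load_dictionary(p)
        assert d.lookup("GO") == [0]

    def test_empty_file_matches_nothing(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("")
        d = load_dictionary(p)
        doc = make_document("x", "BLAST was used.")
        assert match(doc, d) == []

    def test_shared_variant_indexes_both(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Gene Ontology|DB|a|GO\nGene Orthology|SW|b|GO\n")
        d = load_dictionary(p)
        assert sorted(d.lookup("GO")) == [0, 1]
        # conflicting types resolve to an unspecified mention type
        assert d.rtype_of(d.lookup("GO")) == "UNSPECIFIED"

    def test_unknown_rtype_names_line(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Good|DB|a\nBad|XX|a\n")
        with pytest.raises(DictionaryError, match=":2"):
            load_dictionary(p)

    def test_blank_canonical_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(" |DB|a\n")
        with pytest.raises(DictionaryError):
            load_dictionary(p)

    def test_save_load_roundtrip(self, tmp_path, toy_dict):
        p = tmp_path / "d.tsv"
        dc.save_dictionary(toy_dict, p)
        d2 = load_dictionary(p)
        assert d2.unique_variants() == toy_dict.unique_variants()


class TestMatch:
    def test_direct_lookup(self, tiny_dict):
        doc = make_document("x", "we ran BLAST against it")
        ms = match(doc, tiny_dict)
        assert [(m.surface, m.source) for m in ms] == [("BLAST", "dictionary")]

    def test_go_identifier_not_matched_with_preserving_tokens(self, tiny_dict):
        doc = make_document("x", "annotated with GO:0007089 today")
        assert match(doc, tiny_dict) == []

    def test_go_identifier_matched_when_both_guards_off(self, tiny_dict):
        doc = make_document("x", "annotated with GO:0007089 today",
                            preserve_identifiers=False)
        policy = MatchPolicy(go_suppression=False)
        ms = match(doc, tiny_dict, policy)
        assert [m.surface for m in ms] == ["GO"]
        # suppression alone blocks the identifier prefix
        assert match(doc, tiny_dict, MatchPolicy(go_suppression=True)) == []

    def test_longest_match_wins(self):
        d = ResourceDictionary([
            dc.DictionaryEntry("Gene Ontology", "DB", "t"),
            dc.DictionaryEntry("Gene", "DB", "t"),
        ])
        doc = make_document("x", "the Gene Ontology resource")
        ms = match(doc, d)
        assert [m.surface for m in ms] == ["Gene Ontology"]

    def test_case_policy(self):
        d = ResourceDictionary([dc.DictionaryEntry("BLAST", "SW", "t"),
                                dc.DictionaryEntry("UniProt", "DB", "t")])
        # short/all-caps names stay case-sensitive
        doc = make_document("x", "the blast results")
        assert match(doc, d) == []
        # longer mixed-case names also match case-insensitively
        doc = make_document("x", "stored in UNIPROT today")
        assert [m.surface for m in match(doc, d)] == ["UNIPROT"]

    def test_matches_sorted_and_disjoint(self, toy_dict, small_corpus):
        for doc, _ in small_corpus:
            ms = match(doc, toy_dict)
            for a, b in zip(ms, ms[1:]):
                assert a.end <= b.start

    def test_removing_entry_never_adds_matches(self, toy_dict, small_corpus):
        doc = small_corpus[0][0]
        full = match(doc, toy_dict)
        for e in toy_dict.entries[:10]:
            reduced = toy_dict.without_entries({e.canonical})
            assert len(match(doc, reduced)) <= len(full)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data())
    def test_bruteforce_oracle(self, data):
        """Leftmost-longest matching equals exhaustive n-gram enumeration on
        small documents and dictionaries."""
        vocab = ["Alpha", "Beta", "Gamma Tool", "DELTA", "ep9", "Zeta Suite"]
        names = data.draw(st.sets(st.sampled_from(vocab), min_size=1))
        d = ResourceDictionary([dc.DictionaryEntry(n, "SW", "t")
                                for n in names])
        words = data.draw(st.lists(
            st.sampled_from(["Alpha", "Beta", "Gamma", "Tool", "DELTA", "ep9",
                             "the", "ran", "Zeta", "Suite"]),
            min_size=1, max_size=25))
        doc = make_document("x", " ".join(words) + ".")
        got = [(m.start, m.end) for m in
               match(doc, d, MatchPolicy(expand_abbreviations=False))]

        # oracle: all token n-gram hits, then leftmost-longest selection
        hits = []
        toks = doc.tokens
        for i in range(len(toks)):
            for j in range(i + 1, len(toks) + 1):
                surf = " ".join(doc.text[toks[i].start:toks[j - 1].end].split())
                if d.lookup(surf):
                    hits.append((toks[i].start, toks[j - 1].end))
        chosen, cursor = [], -1
        for start in sorted({s for s, _ in hits}):
            if start < cursor:
                continue
            best = max(e for s, e in hits if s == start)
            chosen.append((start, best))
            cursor = best
        assert got == chosen

    def test_full_recall_on_in_dictionary_corpus(self, toy_dict):
        """When every gold surface is a dictionary variant and no ambiguity
        is injected, matching is perfect under strict evaluation."""
        cfg = SynthConfig(n_docs=8, mentions_per_doc=10, novel_name_rate=0.0,
                          ambiguity_rate=0.0, seed=21)
        corpus = generate_corpus(cfg, toy_dict)
        gold = [m for _, ms in corpus for m in ms]
        pred = [m for doc, _ in corpus for m in match(doc, toy_dict)]
        res = compare_mentions(gold, pred, "strict")
        assert res.precision == 100.0 and res.recall == 100.0


class TestAbbreviations:
    def test_long_form_short_form_pair(self):
        doc = make_document(
            "x", "the Database of Interacting Proteins (DIP) lists pairs")
        pairs = detect_abbreviations(doc)
        assert len(pairs) == 1
        (lf, sf) = pairs[0]
        assert doc.text[lf[0]:lf[1]] == "Database of Interacting Proteins"
        assert sf == "DIP"

    def test_letter_overlap_required(self):
        doc = make_document("x", "about two percent (2 %) of cases")
        assert detect_abbreviations(doc) == []

    def test_no_parentheses(self):
        doc = make_document("x", "nothing to expand here")
        assert detect_abbreviations(doc) == []

    def test_short_form_enables_second_pass_match(self):
        d = ResourceDictionary([
            dc.DictionaryEntry("Database of Interacting Proteins", "DB", "t")])
        doc = make_document(
            "x", "the Database of Interacting Proteins (DIP) lists pairs. "
                 "We queried DIP again.")
        ms = match(doc, d, MatchPolicy(expand_abbreviations=True))
        surfaces = [m.surface for m in ms]
        assert surfaces.count("DIP") == 2
        ms_off = match(doc, d, MatchPolicy(expand_abbreviations=False))
        assert [m.surface for m in ms_off] == \
            ["Database of Interacting Proteins"]


class TestAmbiguityReport:
    def test_case_sensitive_overlap(self):
        report = ambiguity_report({"analysis", "UniProt"},
                                  {"english": {"analysis", "cycle"}})
        assert report["english"][1] == 1 and report["english"][0] == {"analysis"}

    def test_empty_names(self):
        report = ambiguity_report(set(), {"english": {"a", "b"}})
        assert report["english"] == (set(), 0)

    def test_case_policy_changes_counts(self):
        cs = ambiguity_report({"Blast"}, {"english": {"blast"}},
                              case_sensitive=True)
        ci = ambiguity_report({"Blast"}, {"english": {"blast"}},
                              case_sensitive=False)
        assert cs["english"][1] == 0 and ci["english"][1] == 1
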