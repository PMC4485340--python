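"""Document model, tokenisation, standoff I/O and B-I-O conversion."""

import pytest
from hypothesis import given, settings, strategies as st

from resner import corpus as c
from resner import (CorpusError, LabelSequence, Mention, bio_to_mentions,
                    make_document, mentions_to_bio, tokenize, write_conll)


class TestTokenize:
    def test_word_punct_split(self):
        tokens, sentences = tokenize("BLAST was run.")
        assert [t.text for t in tokens] == ["BLAST", "was", "run", "."]
        assert sentences == [(0, 4)]

    def test_single_char(self):
        tokens, _ = tokenize("a")
        assert (tokens[0].start, tokens[0].end) == (0, 1)

    def test_identifier_preserving_modes(self):
        tokens, _ = tokenize("GO:0007089")
        assert [t.text for t in tokens] == ["GO:0007089"]
        tokens, _ = tokenize("GO:0007089", preserve_identifiers=False)
        assert [t.text for t in tokens] == ["GO", ":", "0007089"]

    def test_decimal_number_kept_whole(self):
        tokens, sentences = tokenize("version 1.83 was used.")
        assert "1.83" in [t.text for t in tokens]
        assert len(sentences) == 1

    def test_empty_text_rejected(self):
        with pytest.raises(CorpusError):
            tokenize("")
        with pytest.raises(CorpusError):
            tokenize("   ")

    def test_sentence_split(self):
        _, sentences = tokenize("First here. Second there.")
        assert len(sentences) == 2

    def test_token_invariants_and_coverage(self):
        text = "We used MySQL v5; results (n=3) follow."
        doc = make_document("d", text)
        doc.validate()
        # every non-whitespace char is covered by exactly one token
        covered = set()
        for t in doc.tokens:
            covered.update(range(t.start, t.end))
        expected = {i for i, ch in enumerate(text) if not ch.isspace()}
        assert covered == expected


class TestBioConversion:
    def test_simple_projection(self):
        doc = make_document("d", "used BLAST here")
        seq = mentions_to_bio(doc, [Mention("d", 5, 10, "BLAST")])
        assert seq.labels == ["O", "B", "O"]

    def test_multi_token_mention(self):
        doc = make_document("d", "Gene Ontology terms")
        seq = mentions_to_bio(doc, [Mention("d", 0, 13, "Gene Ontology")])
        assert seq.labels == ["B", "I", "O"]

    def test_no_mentions_all_outside(self):
        doc = make_document("d", "no names here")
        assert mentions_to_bio(doc, []).labels == ["O"] * 3

    def test_overlap_rejected(self):
        doc = make_document("d", "Gene Ontology terms")
        with pytest.raises(CorpusError):
            mentions_to_bio(doc, [Mention("d", 0, 13, "Gene Ontology"),
                                  Mention("d", 5, 18, "Ontology term")])

    def test_misaligned_snapped_outward(self, caplog):
        doc = make_document("d", "the BLASTED run")
        with caplog.at_level("WARNING", logger="resner"):
            seq = mentions_to_bio(doc, [Mention("d", 4, 9, "BLAST")])
        assert seq.labels == ["O", "B", "O"]
        assert any("snapped" in r.message for r in caplog.records)
        back = bio_to_mentions(doc, seq)
        assert (back[0].start, back[0].end) == (4, 11)

    def test_decode_runs(self):
        doc = make_document("d", "ran Gene Ontology fast")
        ms = bio_to_mentions(doc, LabelSequence("d", ["O", "B", "I", "O"]))
        assert [m.surface for m in ms] == ["Gene Ontology"]
        assert bio_to_mentions(doc, LabelSequence("d", ["O"] * 4)) == []

    def test_single_token_b(self):
        doc = make_document("d", "BLAST")
        ms = bio_to_mentions(doc, LabelSequence("d", ["B"]))
        assert len(ms) == 1 and ms[0].surface == "BLAST"

    def test_length_mismatch_rejected(self):
        doc = make_document("d", "one two")
        with pytest.raises(CorpusError):
            bio_to_mentions(doc, LabelSequence("d", ["O"]))

    @settings(derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_roundtrip_identity(self, data):
        """mentions -> B-I-O -> mentions is the identity for token-aligned,
        non-overlapping mentions on random documents."""
        words = data.draw(st.lists(
            st.sampled_from(["alpha", "Tool", "GO", "beta", "SeqKit", "x9"]),
            min_size=1, max_size=12))
        text = " ".join(words)
        doc = make_document("d", text)
        # choose a random subset of non-adjacent tokens as 1-token mentions
        picks = data.draw(st.sets(
            st.integers(min_value=0, max_value=len(doc.tokens) - 1)))
        mentions = [Mention("d", t.start, t.end, t.text)
                    for k, t in enumerate(doc.tokens) if k in picks]
        seq = mentions_to_bio(doc, mentions)
        back = bio_to_mentions(doc, seq)
        assert [(m.start, m.end) for m in back] == \
               sorted((m.start, m.end) for m in mentions)


class TestStandoff:
    def test_write_read_roundtrip(self, tmp_path, small_corpus):
        c.write_standoff(small_corpus, tmp_path)
        loaded = c.read_standoff(tmp_path)
        assert len(loaded) == len(small_corpus)
        for (d1, m1), (d2, m2) in zip(sorted(small_corpus, key=lambda p: p[0].doc_id),
                                      loaded):
            assert d1.text == d2.text
            assert [(m.start, m.end) for m in sorted(m1, key=lambda m: m.start)] \
                == [(m.start, m.end) for m in m2]

    def test_basic_pair(self, tmp_path):
        (tmp_path / "a.txt").write_text("used BLAST")
        (tmp_path / "a.ann").write_text("T1\tSoftware 5 10\tBLAST\n")
        [(doc, ms)] = c.read_standoff(tmp_path)
        assert (ms[0].start, ms[0].end, ms[0].surface) == (5, 10, "BLAST")

    def test_offset_beyond_text_is_load_error(self, tmp_path):
        (tmp_path / "a.txt").write_text("short")
        (tmp_path / "a.ann").write_text("T1\tSoftware 0 99\tshort\n")
        with pytest.raises(CorpusError, match="a.ann"):
            c.read_standoff(tmp_path)

    def test_overlapping_gold_is_load_error(self, tmp_path):
        (tmp_path / "a.txt").write_text("Gene Ontology terms")
        (tmp_path / "a.ann").write_text(
            "T1\tDatabase 0 13\tGene Ontology\nT2\tDatabase 5 13\tOntology\n")
        with pytest.raises(CorpusError, match="overlap"):
            c.read_standoff(tmp_path)

    def test_empty_ann_gives_no_mentions(self, tmp_path):
        (tmp_path / "a.txt").write_text("plain text here")
        (tmp_path / "a.ann").write_text("")
        [(_, ms)] = c.read_standoff(tmp_path)
        assert ms == []

    def test_jsonl_roundtrip(self, tmp_path, small_corpus):
        path = tmp_path / "c.jsonl"
        c.write_jsonl(small_corpus, path)
        loaded = c.read_jsonl(path)
        assert [(d.doc_id, d.text) for d, _ in loaded] == \
               [(d.doc_id, d.text) for d, _ in small_corpus]


class TestConll:
    def test_layout_and_roundtrip(self):
        doc = make_document("d", "Run BLAST now. Done.")
        seq = mentions_to_bio(doc, [Mention("d", 4, 9, "BLAST")])
        text = write_conll(doc, seq)
        blocks = text.strip().split("\n\n")
        assert len(blocks) == 2  # one block per sentence
        parsed = c.read_conll(text)
        flat = [(tok, lab) for sent in parsed for tok, _, lab in sent]
        assert flat == [(t.text, l) for t, l in zip(doc.tokens, seq.labels)]

    def test_labels_serialised_literally(self):
        doc = make_document("d", "Gene Ontology")
        text = write_conll(doc, LabelSequence("d", ["B", "I"]))
        lines = [l for l in text.splitlines() if l]
        assert lines[0].endswith("\tB") and lines[1].endswith("\tI")
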