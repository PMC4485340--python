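import pytest

from resner import (Mention, ResourceDictionary, make_document)
from resner.dictionary import DictionaryEntry
from resner.synth import SynthConfig, generate_corpus, make_toy_dictionary


@pytest.fixture(scope="session")
def tiny_dict() -> ResourceDictionary:
    return ResourceDictionary([
        DictionaryEntry("BLAST", "SW", "t"),
        DictionaryEntry("Gene Ontology", "DB", "t", {"GO"}),
        DictionaryEntry("UniProt", "DB", "t", {"Uniprot"}),
        DictionaryEntry("analysis", "PK", "t"),
    ])


@pytest.fixture(scope="session")
def toy_dict() -> ResourceDictionary:
    return make_toy_dictionary(60, seed=11)


@pytest.fixture(scope="session")
def small_corpus(toy_dict):
    cfg = SynthConfig(n_docs=10, mentions_per_doc=10, seed=11)
    return generate_corpus(cfg, toy_dict)


@pytest.fixture()
def doc_with_mentions():
    doc = make_document("d1", "We ran BLAST against the Gene Ontology terms.")
    mentions = [
        Mention("d1", 7, 12, "BLAST"),
        Mention("d1", 25, 38, "Gene Ontology"),
    ]
    assert doc.text[7:12] == "BLAST" and doc.text[25:38] == "Gene Ontology"
    return doc, mentions
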