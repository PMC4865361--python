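import json
import random

import pytest

from beltrace.corpus import (
    Document,
    build_index,
    doc_sentences,
    load_index,
    read_jsonl_corpus,
    read_pubmed_xml,
    retrieve_citations,
    save_index,
    score_document,
    split_sentences,
    tokenize,
)
from beltrace.lexicons import EntityLexicon
from beltrace.model import parse_statement
from beltrace.query import translate_statement

from oracles import brute_force_retrieve

PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>11111</PMID>
      <Article>
        <ArticleTitle>TNF signalling in neutrophils.</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Exposure to LPS was studied.</AbstractText>
          <AbstractText Label="RESULTS">TNF increased CREB phosphorylation.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>22222</PMID>
      <Article>
        <ArticleTitle>A study without an abstract.</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


def test_read_pubmed_xml_records(tmp_path):
    p = tmp_path / "pm.xml"
    p.write_text(PUBMED_XML, encoding="utf-8")
    docs = read_pubmed_xml(p)
    assert [d.doc_id for d in docs] == ["11111", "22222"]
    assert all(d.source == "abstract" for d in docs)
    # structured abstract segments joined with single spaces
    assert docs[0].body == "Exposure to LPS was studied. TNF increased CREB phosphorylation."
    assert docs[1].body == ""


def test_read_pubmed_xml_skips_records_without_pmid(tmp_path, caplog):
    xml = PUBMED_XML.replace("<PMID>22222</PMID>", "")
    p = tmp_path / "pm.xml"
    p.write_text(xml, encoding="utf-8")
    with caplog.at_level("WARNING"):
        docs = read_pubmed_xml(p)
    assert [d.doc_id for d in docs] == ["11111"]


def test_read_pubmed_xml_malformed_raises(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text("<PubmedArticleSet><oops>", encoding="utf-8")
    with pytest.raises(ValueError, match="malformed"):
        read_pubmed_xml(p)


def test_read_jsonl_corpus(tmp_path):
    p = tmp_path / "c.jsonl"
    rows = [
        {"id": "A1", "source": "fulltext", "title": "t1", "text": "b1"},
        {"id": "A2", "title": "t2", "text": "b2"},  # source defaults
        {"id": "A3", "source": "abstract", "title": "t3", "text": "b3"},
    ]
    p.write_text("".join(json.dumps(r) + "\n" for r in rows), encoding="utf-8")
    docs = read_jsonl_corpus(p)
    assert [d.doc_id for d in docs] == ["A1", "A2", "A3"]
    assert docs[1].source == "abstract"


def test_read_jsonl_rejects_bad_line_and_duplicates(tmp_path):
    p = tmp_path / "c.jsonl"
    p.write_text('{"id": "A1", "title": "t", "text": "x"}\nnot json\n', encoding="utf-8")
    with pytest.raises(ValueError, match=":2"):
        read_jsonl_corpus(p)
    p.write_text(
        '{"id": "A1", "title": "t", "text": "x"}\n{"id": "A1", "title": "t", "text": "y"}\n',
        encoding="utf-8",
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_jsonl_corpus(p)


# -- sentence splitting ------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("We showed X. We demonstrate Y.", ["We showed X.", "We demonstrate Y."]),
    ("HSF1 (Fig. 2) is phosphorylated.", ["HSF1 (Fig. 2) is phosphorylated."]),
    ("Smith et al. reported this. We disagree.",
     ["Smith et al. reported this.", "We disagree."]),
    ("Serine 133 is modified. 520 is not.",
     ["Serine 133 is modified.", "520 is not."]),
    ("", []),
])
def test_split_sentences(text, expected):
    assert [text[s:e] for s, e in split_sentences(text)] == expected


def test_split_offsets_partition_text_modulo_whitespace(synthetic):
    for doc in synthetic.documents[:40]:
        text = doc.text
        spans = split_sentences(text)
        assert all(0 <= s < e <= len(text) for s, e in spans)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
        leftover = text
        for s, e in reversed(spans):
            leftover = leftover[:s] + leftover[e:]
        assert leftover.strip() == ""


def test_doc_sentences_title_is_sentence_zero():
    doc = Document("D1", "abstract", "A title", "First body sentence. Second one.")
    sents = doc_sentences(doc)
    assert [s.text for s in sents] == ["A title", "First body sentence.", "Second one."]
    assert [s.sent_index for s in sents] == [0, 1, 2]
    assert doc.text[sents[1].char_start:sents[1].char_end] == "First body sentence."


# -- index statistics --------------------------------------------------------

def test_index_statistics_consistent():
    idx = build_index([Document("D1", "abstract", "", "TNF TNF creb1")])
    assert idx.postings["tnf"]["D1"] == 2
    assert idx.postings["creb1"]["D1"] == 1
    assert idx.doc_lengths["D1"] == 3
    assert idx.n_docs == 1


def test_index_term_totals_match_corpus_counts(synthetic_index):
    idx = synthetic_index
    for term in list(idx.postings)[:50]:
        total = sum(idx.postings[term].values())
        recount = sum(tokens.count(term) for tokens in idx.doc_tokens.values())
        assert total == recount
    assert idx.n_docs == len(idx.documents)


def test_empty_corpus_retrieves_nothing():
    idx = build_index([])
    q = translate_statement(parse_statement("p(HGNC:A) increases p(HGNC:B)"))
    assert retrieve_citations(idx, q) == []


# -- scoring -----------------------------------------------------------------

def _single_term_query(term_surface, weight=2.0):
    from beltrace.query import ClauseGroup, QueryTerm, TranslatedQuery

    stmt = parse_statement(f"p(HGNC:{term_surface}) increases p(HGNC:{term_surface})")
    group = ClauseGroup(
        (QueryTerm(term_surface, weight),), required=True, kind="entity",
        label=f"HGNC:{term_surface}",
    )
    return TranslatedQuery((group,), stmt)


def test_bm25_scores_match_independent_recomputation():
    docs = [
        Document("D1", "abstract", "", "tnf activates creb1 signaling"),
        Document("D2", "abstract", "", "tnf binds tnf receptor"),
        Document("D3", "abstract", "", "unrelated text here"),
    ]
    idx = build_index(docs)
    q = _single_term_query("tnf")
    scores = {d.doc_id: score_document(idx, q, d.doc_id) for d in docs}
    assert scores["D2"] > scores["D1"] > scores["D3"] == 0.0
    oracle = dict(brute_force_retrieve(docs, q, 1000))
    for doc_id in ("D1", "D2"):
        assert scores[doc_id] == pytest.approx(oracle[doc_id])


def test_score_is_linear_in_weights():
    from dataclasses import replace

    from beltrace.query import QueryTerm, TranslatedQuery

    docs = [Document("D1", "abstract", "", "tnf activates creb1 and tnf")]
    idx = build_index(docs)
    q = translate_statement(parse_statement("p(HGNC:tnf) increases p(HGNC:creb1)"))
    doubled = TranslatedQuery(
        tuple(
            replace(g, terms=tuple(QueryTerm(t.surface, 2 * t.weight) for t in g.terms))
            for g in q.groups
        ),
        q.statement,
    )
    assert score_document(idx, doubled, "D1") == pytest.approx(
        2 * score_document(idx, q, "D1")
    )


def test_absent_term_contributes_zero():
    docs = [Document("D1", "abstract", "", "alpha beta gamma")]
    idx = build_index(docs)
    q = _single_term_query("zeta")
    assert score_document(idx, q, "D1") == 0.0


def test_unknown_doc_id_raises():
    idx = build_index([Document("D1", "abstract", "", "x")])
    with pytest.raises(KeyError):
        score_document(idx, _single_term_query("x"), "D9")


# -- retrieval vs brute force ------------------------------------------------

_VOCAB = ["tnf", "creb1", "hsf1", "il6", "binds", "signal", "cell", "mouse",
          "kinase", "pathway"]


def _random_corpus(rng, n_docs):
    docs = []
    for i in range(n_docs):
        words = [rng.choice(_VOCAB) for _ in range(rng.randint(3, 20))]
        docs.append(Document(
            f"D{i:03d}", rng.choice(["abstract", "fulltext"]),
            rng.choice(_VOCAB), " ".join(words),
        ))
    return docs


def _random_query(rng):
    e1, e2 = rng.sample(["tnf", "creb1", "hsf1", "il6"], 2)
    stmt = parse_statement(f"p(HGNC:{e1}) increases p(HGNC:{e2})")
    lex = EntityLexicon()
    if rng.random() < 0.5:
        lex.add("HGNC", e1, "kinase pathway")  # multi-word phrase synonym
    return translate_statement(stmt, lex)


def test_retrieval_matches_brute_force_oracle_on_random_corpora():
    rng = random.Random(1234)
    for trial in range(200):
        docs = _random_corpus(rng, rng.randint(1, 50))
        q = _random_query(rng)
        cap = rng.choice([2, 5, 1000])
        got = retrieve_citations(build_index(docs), q, cap_per_source=cap)
        expected = brute_force_retrieve(docs, q, cap_per_source=cap)
        assert [d for d, _ in got] == [d for d, _ in expected]
        for (_, a), (_, b) in zip(got, expected):
            assert a == pytest.approx(b)


def test_returned_documents_satisfy_required_groups():
    rng = random.Random(99)
    docs = _random_corpus(rng, 50)
    q = _random_query(rng)
    got = retrieve_citations(build_index(docs), q)
    by_id = {d.doc_id: d for d in docs}
    for doc_id, _ in got:
        text_tokens = tokenize(by_id[doc_id].text)
        for group in q.required_groups():
            assert any(
                tokenize(t.surface) == text_tokens[i:i + len(tokenize(t.surface))]
                for t in group.terms
                for i in range(len(text_tokens))
            )


def test_cap_per_source_limits_results():
    docs = [Document(f"D{i}", "abstract", "", "tnf creb1 site") for i in range(5)]
    idx = build_index(docs)
    q = translate_statement(parse_statement("p(HGNC:tnf) increases p(HGNC:creb1)"))
    assert len(retrieve_citations(idx, q, cap_per_source=2)) == 2


def test_index_round_trip_through_json(tmp_path, synthetic):
    idx = build_index(synthetic.documents[:20])
    p = tmp_path / "index.json"
    save_index(idx, p)
    again = load_index(p)
    assert again.postings == idx.postings
    assert again.doc_lengths == idx.doc_lengths
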