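import random

import pytest

from beltrace.corpus import Document, build_index, doc_sentences
from beltrace.lexicons import EntityLexicon, default_trigger_lexicon
from beltrace.model import parse_statement
from beltrace.ranking import (
    RankWeights,
    detect_elements,
    entity_filter,
    rank_evidence,
    score_sentence,
)

PMOD_STMT = parse_statement("p(HGNC:MAPT) increases p(HGNC:GSK3B,pmod(P,S,520))")


def _kinds(matches):
    return {(m.kind, m.key) for m in matches}


def test_pmod_argument_cues_detected():
    sent = "MAPT activates GSK3B via phosphorylation of serine 520 in vivo"
    matches = detect_elements(sent, PMOD_STMT)
    got = _kinds(matches)
    assert ("function_arg", "mod:P") in got
    assert ("function_arg", "residue:S") in got
    assert ("function_arg", "pos:520") in got
    assert ("entity_exact", "HGNC:MAPT") in got
    assert ("relation", "increase") in got


def test_curated_creb_sentence_fires_all_modification_cues():
    stmt = parse_statement("p(MGI:TNF) increases p(MGI:CREB1,pmod(P,S,133))")
    lex = EntityLexicon()
    lex.add("MGI", "CREB1", "CREB")
    sent = ("Exposure of neutrophils to LPS or TNF-a resulted in increased levels "
            "of the transcriptionally active serine 133-phosphorylated form of CREB")
    matches = detect_elements(sent, stmt, lex)
    got = _kinds(matches)
    assert ("function_arg", "mod:P") in got      # "phosphorylated"
    assert ("function_arg", "residue:S") in got  # "serine"
    assert ("function_arg", "pos:133") in got    # literal position
    assert ("entity_synonym", "MGI:CREB1") in got
    assert ("relation", "increase") in got       # "increased"


def test_no_elements_no_matches():
    assert detect_elements("completely unrelated prose", PMOD_STMT) == []


def test_matches_are_presence_not_count():
    sent = "GSK3B GSK3B GSK3B phosphorylation phosphorylation"
    matches = detect_elements(sent, PMOD_STMT)
    keys = [(m.kind, m.key) for m in matches]
    assert len(keys) == len(set(keys))


def test_word_boundary_matching_rejects_substrings():
    matches = detect_elements("MAPT2 interacts with GSK3B4", PMOD_STMT)
    assert ("entity_exact", "HGNC:MAPT") not in _kinds(matches)


def test_entity_filter_requires_all_entities():
    stmt = parse_statement("p(HGNC:TNF) increases p(HGNC:CREB1)")
    lex = EntityLexicon()
    lex.add("HGNC", "CREB1", "CREB")
    only_one = detect_elements("TNF does something", stmt, lex)
    assert entity_filter(only_one, stmt) is False
    both = detect_elements("TNF binds CREB in cells", stmt, lex)
    assert entity_filter(both, stmt) is True  # one exact + one synonym
    assert entity_filter([], stmt) is False


def test_extra_matches_never_lower_the_score():
    base = detect_elements("MAPT inhibits nothing GSK3B", PMOD_STMT)
    richer = detect_elements("MAPT activates GSK3B phosphorylation serine 520", PMOD_STMT)
    assert score_sentence(richer) > score_sentence(base)


def test_position_argument_breaks_ties_upward():
    a = detect_elements("MAPT activates GSK3B phosphorylation of serine", PMOD_STMT)
    b = detect_elements("MAPT activates GSK3B phosphorylation of serine 520", PMOD_STMT)
    assert score_sentence(b) > score_sentence(a)


def test_exact_entity_outweighs_synonym():
    stmt = parse_statement("p(HGNC:TNF) increases p(HGNC:CREB1)")
    lex = EntityLexicon()
    lex.add("HGNC", "TNF", "cachectin")
    exact = detect_elements("TNF binds CREB1", stmt, lex)
    synonym = detect_elements("cachectin binds CREB1", stmt, lex)
    assert score_sentence(exact) > score_sentence(synonym)


def test_classifier_bonus_is_additive_only():
    matches = detect_elements("MAPT activates GSK3B", PMOD_STMT)
    w = RankWeights()
    assert score_sentence(matches, w, classifier_agrees=True) == (
        score_sentence(matches, w, classifier_agrees=False) + w.classifier_bonus
    )


def test_weight_hierarchy_enforced():
    with pytest.raises(ValueError):
        RankWeights(entity_exact=1.0)  # below entity_synonym default
    w = RankWeights()
    assert w.entity_exact > w.entity_synonym >= w.function_arg > w.function > w.relation


def test_weight_hierarchy_orders_single_difference_pairs():
    # two sentences identical except one match of a higher-ranked kind
    stmt = parse_statement("p(HGNC:TNF) increases p(HGNC:CREB1,pmod(P))")
    lex = EntityLexicon()
    lex.add("HGNC", "TNF", "cachectin")
    higher = detect_elements("TNF and CREB1", stmt, lex)       # exact + exact
    lower = detect_elements("cachectin and CREB1", stmt, lex)  # synonym + exact
    assert score_sentence(higher) > score_sentence(lower)
    arg = detect_elements("TNF CREB1 phosphorylation", stmt, lex)
    fn = detect_elements("TNF CREB1 modification", stmt, lex)  # pmod function trigger
    rel = detect_elements("TNF CREB1 increased", stmt, lex)
    assert score_sentence(arg) > score_sentence(fn) > score_sentence(rel)


# -- end-to-end ranking ------------------------------------------------------

def _full_gold(synthetic):
    gold = {}
    for g in synthetic.gold:
        if g.relevance == "full":
            gold.setdefault(g.query_id, set()).add((g.doc_id, g.sent_index))
    return gold


def test_planted_evidence_recall_at_10(synthetic, synthetic_index):
    gold = _full_gold(synthetic)
    found = total = 0
    for qid, stmt in synthetic.statements.items():
        out = rank_evidence(stmt, synthetic_index, synthetic.entity_lexicon)
        got = {(c.sentence.doc_id, c.sentence.sent_index) for c in out}
        total += len(gold[qid])
        found += len(gold[qid] & got)
    assert found / total >= 0.9


def test_output_always_at_most_ten(synthetic, synthetic_index):
    for stmt in synthetic.statements.values():
        out = rank_evidence(stmt, synthetic_index, synthetic.entity_lexicon)
        assert len(out) <= 10
        assert [c.rank for c in out] == list(range(1, len(out) + 1))


def test_returned_sentences_pass_entity_filter_end_to_end(synthetic, synthetic_index):
    lex = synthetic.entity_lexicon
    for stmt in synthetic.statements.values():
        for cand in rank_evidence(stmt, synthetic_index, lex):
            rescanned = detect_elements(cand.sentence.text, stmt, lex)
            assert entity_filter(rescanned, stmt)


def test_no_cooccurrence_yields_empty_result():
    docs = [
        Document("D1", "abstract", "", "IL1A alone in this sentence"),
        Document("D2", "abstract", "", "DEFB4A alone in this one"),
    ]
    idx = build_index(docs)
    stmt = parse_statement("p(HGNC:IL1A) increases r(HGNC:DEFB4A)")
    assert rank_evidence(stmt, idx) == []


def test_ranking_invariant_under_document_order_permutation(synthetic):
    rng = random.Random(5)
    docs = list(synthetic.documents)
    rng.shuffle(docs)
    shuffled_index = build_index(docs)
    reference_index = build_index(synthetic.documents)
    for qid in list(synthetic.statements)[:10]:
        stmt = synthetic.statements[qid]
        a = rank_evidence(stmt, reference_index, synthetic.entity_lexicon)
        b = rank_evidence(stmt, shuffled_index, synthetic.entity_lexicon)
        assert [(c.sentence.doc_id, c.sentence.sent_index) for c in a] == [
            (c.sentence.doc_id, c.sentence.sent_index) for c in b
        ]
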