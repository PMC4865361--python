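# beltrace

Evidence-sentence retrieval and ranking for Biological Expression
Language (BEL) statements.

Curating causal biological networks means pairing every BEL statement —
a triple like

```
p(MGI:TNF) increases p(MGI:CREB1,pmod(P,S,133))
```

— with the literature sentences that support it. Doing this by hand over
millions of abstracts is the bottleneck of network curation. beltrace
automates the retrieval side: given a statement, it

1. **translates** it into a weighted boolean query — every entity is a
   mandatory OR-group (`AND` across entities) with the curated name
   boosted 2:1 over its dictionary synonyms; functions, modification
   arguments (type, residue, literal sequence position) and the relation
   polarity contribute optional trigger-word groups;
2. **retrieves** candidate citations from an in-process inverted index
   with boost-weighted Okapi BM25 (k1 = 1.2, b = 0.75), capped per
   source (abstracts / full texts);
3. **ranks** at most 10 evidence sentences: sentences missing any entity
   are filtered out, the rest score one weight per distinct matched
   element with a strict preference hierarchy (exact entity > synonym ≥
   modification argument > function > relation trigger), plus a bonus
   when a trained increase/decrease classifier agrees with the
   statement's polarity.

For a query with per-query labels TP/FP, the evaluation module computes
precision = TP/(TP+FP), per-query average precision
AP = (1/R) Σ_{i: rel} P@i with R the number of retrieved TPs, mean AP
over queries (MAP), and the worst / random (2000 reshuffles) / best
baselines that bracket the achievable MAP for a fixed label multiset.

A synthetic-corpus module generates statements, corpora with planted
evidence sentences, synonym lexicons, gold labels and classifier
training data, so the whole pipeline is testable without any downloads.

## Worked example

```sh
beltrace simulate --seed 5 -o demo/ --n-statements 5
beltrace index --jsonl demo/corpus.jsonl -o demo/index.json
beltrace query "$(head -1 demo/statements.bel | cut -d'#' -f1)" \
    --index demo/index.json --entity-lex demo/lexicon.tsv
```

prints one JSON record per ranked evidence sentence; with seed 5 the
first statement is `kin(p(MGI:GENA)) decreases p(MGI:GENB,pmod(P,T,422))`
and the top of the ranking is:

```
{"rank": 1, "doc_id": "D000F2", "sent_index": 1, "final_score": 58.0, "sentence": "Vanu gena factor 2 debululi vonasuvu inhibit lero genb factor 1 fodoma sibarute lero denede phosphorylation leva sozemagi nebemiti threonine lime 422 sofo file fugi."}
{"rank": 2, "doc_id": "D000F1", "sent_index": 1, "final_score": 58.0, "sentence": "Duti ginasi nevu GENA ferubaso repressed buzorime genb factor 2 rabo phosphorylation bobo threonine dobo 422 segebu bepana."}
{"rank": 3, "doc_id": "D000F0", "sent_index": 1, "final_score": 34.0, "sentence": "Satebito gena factor 2 ravimu zidegaga decreases lepi pibifuze razi bagasi voziraze GENB rigole."}
{"rank": 4, "doc_id": "D000C0", "sent_index": 1, "final_score": 32.0, "sentence": "Tutabasu GENA tabe barodopu fimi suzagu sibarute lepi laza fugi genb factor 2 bagasi zesuza."}
```

The top sentences are the planted "full" evidence: both entities (name
or synonym), a correct-polarity trigger, and the modification cues. The
score of 58 decomposes as 16 + 16 (both entity names matched at word
boundaries — here inside their synonyms) + 8 + 8 + 8 (modification
type "phosphorylation", residue "threonine", literal position "422")
+ 2 (relation trigger "inhibit"). Rank 3 is a full sentence without the
modification cues (16 + 16 + 2); rank 4 is a "context" sentence —
entities present but no correct-polarity trigger (16 + 16) — and ranks
strictly below every full sentence. Python API:

```python
from beltrace import (parse_statement, build_index, rank_evidence)
stmt = parse_statement("p(HGNC:IL1A) increases r(HGNC:DEFB4A)")
for cand in rank_evidence(stmt, index, entity_lexicon, k=10):
    print(cand.rank, cand.final_score, cand.sentence.text)
```

The library surface mirrors the pipeline: `beltrace.model` (parser /
serializer), `beltrace.lexicons` (synonym and trigger TSVs),
`beltrace.query`, `beltrace.corpus` (PubMed XML / JSONL readers,
sentence splitter, index), `beltrace.classifier` (sklearn-style
estimator + 10-fold CV grid), `beltrace.ranking`, `beltrace.simulate`,
`beltrace.evaluation`.

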