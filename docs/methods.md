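# Methods

## Task and pipeline

Curators of causal biological networks express findings as Biological
Expression Language (BEL) triples — `subject relation object`, e.g.
`p(MGI:TNF) increases p(MGI:CREB1,pmod(P,S,133))` — and must locate, for
each statement, the literature sentences that support it. beltrace
implements this as a three-stage retrieval pipeline:

1. **Query translation.** The statement is parsed into entities
   (namespaced identifiers), functions (`p`, `kin`, `tscript`, …,
   including `pmod` with its type/residue/position arguments) and a
   relation whose four tokens collapse to a binary polarity
   (increase / decrease). Each distinct entity becomes a *required*
   OR-group: the name as written at weight 2, each dictionary synonym at
   weight 1. Functions, modification arguments and the relation polarity
   become *optional* OR-groups of trigger words at weight 1. Entities
   are mandatory because a citation that does not mention every entity
   cannot evidence the statement; everything else only sharpens ranking.

2. **Retrieval.** Documents (abstract or full-text records) are indexed
   whole in an in-process inverted index. Candidates must contain at
   least one term of every required group; they are ranked by
   boost-weighted Okapi BM25 (`k1 = 1.2`, `b = 0.75`,
   `idf = ln(1 + (N − df + 0.5)/(df + 0.5))`), each term's BM25
   contribution multiplied by its group weight. Multi-word synonyms are
   scored as contiguous phrases. At most `cap_per_source` (default
   1000) citations survive per source, abstracts concatenated before
   full texts.

3. **Sentence ranking.** Retrieved citations are split into sentences
   (rule-based splitter with an abbreviation guard; offsets into
   `title + "\n" + body` are exact). Each sentence is scanned with
   case-insensitive, word-boundary, longest-match dictionary lookup for
   the statement's elements. Sentences missing any entity (name or
   synonym) are discarded. Survivors score the sum of one weight per
   *distinct* matched element, by kind:

   | kind | default weight |
   |---|---|
   | exact entity name | 16 |
   | entity synonym | 12 |
   | modification argument (type word, residue word, literal position) | 8 |
   | function trigger | 4 |
   | relation trigger | 2 |
   | classifier agreement bonus | +2 |

   The *hierarchy* is the contract (exact entity > synonym ≥
   modification argument > function > relation); the numbers merely
   encode it and are configurable (`RankWeights`). Presence, not count,
   scores: evidence strength grows with the number of distinct statement
   components a sentence covers, not with repetition. A trained
   increase/decrease classifier adds a bonus when its prediction agrees
   with the statement polarity; it never penalises, so lexical evidence
   cannot be vetoed by a soft prediction. Ties break by citation
   retrieval score, then document id, then sentence index, making
   ranking invariant to corpus order. At most 10 sentences are returned.

## Relation classifier

A binary increase/decrease sentence classifier over sparse lexical
features: `uni:` unigram counts (stopwords and entity tokens excluded),
`bi:` bigrams over the stopword-filtered stream with each entity span
collapsed to an `ENTITY` placeholder, `ent:` per-entity indicators, and
`pos:` position-indexed part-of-speech tags of the tokens strictly
between the first and last entity span. Features occurring in fewer than
`min_feature_df = 2` training sentences are dropped — hapax n-grams
carry no generalizable signal and dilute naive Bayes likelihoods. POS
tagging is a pluggable `token -> tag` callable; the default is a small
closed-class lexicon plus suffix heuristics, which is coarse but
sufficient for the `pos:` family. Three model families are exposed
(multinomial naive Bayes, random forest, linear SVM — margin distances
squashed through a logistic for the confidence) behind one
sklearn-compatible estimator. `cross_validate` produces the 3 models ×
3 cumulative feature sets (`uni`, `uni+pos`, `uni+pos+bi`) macro-F grid
under seeded stratified k-fold, bit-reproducible for a fixed seed.
Macro-averaged F is used; with balanced classes it is insensitive to the
choice of positive class.

## Evaluation

Each returned sentence is judged TP/FP under nested criteria — *full*
(supports the complete statement) ⊂ *relaxed* ⊂ *context* (mentions all
entities in a relevant setting). Precision is TP/(TP+FP) over all
returned sentences. Ranking quality is mean average precision; the AP
denominator is the number of TPs *retrieved*, because only returned
sentences carry judgments (recall-normalised AP is not computable in
this protocol). Every MAP is bracketed by three baselines computed on
the same per-query label multisets: worst (TPs after FPs), best (TPs
first), and random (mean MAP over 2000 independent per-query reshuffles,
seeded). Reports additionally stratify queries by entity namespace into
groups with/without at least one full-relevant returned sentence, with
rounded integer percentages.

## Synthetic study design

Desk-scale testing replaces the PubMed-scale index and human judgments
with a generator whose defaults define the study conditions: 50
statements (two invented entities each, namespaces HGNC/MGI, 2 synonyms
per entity; half the statements carry a `pmod(P, residue, position)`
argument and 30% a `kin()` wrapper), 3 planted *full* sentences and 2
*context* sentences per statement (each in its own document, random
abstract/full-text source), and 50 distractor documents. A full sentence
contains every entity (name or synonym), a correct-polarity trigger,
and — for modified statements, with probability 0.7 — the modification
cues; a context sentence contains the entities with a wrong or absent
trigger; a distractor contains at most one entity and therefore can
never satisfy a statement's mandatory groups. All vocabulary is
synthetic: noise tokens are pseudo-words screened against the trigger
dictionary and the `gen…` name prefix, so separability is by
construction, not accident. Sentences are 8–16 noise tokens around the
insertions.

Classifier data are 400 balanced sentences embedding a contiguous
subject–trigger–object core (the SVO adjacency of causal prose;
occasionally one intervening noise word) with 8 trigger words per
polarity, disjoint between classes. A `trigger_overlap` dial draws the
trigger from the pooled vocabulary with the given probability: 0 is
fully separable, 1 removes all class signal (expected macro-F ≈ 0.5).

What passing these tests does **not** show: robustness to real
biomedical language — inflected and nested entity mentions, negation and
speculation, anaphora, trigger words outside the dictionary, sentence
boundaries in malformed text, or class imbalance. The generator
validates the pipeline's mechanics (filtering, weighting, ordering,
bookkeeping), not its linguistic coverage.

## Numerical and design choices

- BM25 with the common defaults stands in for an external search
  engine's unpublished similarity; parameters are arguments.
- No stemming at retrieval (reproducibility; surface-token matching),
  synonyms handle morphology where supplied.
- Phrase document frequency is computed by scanning candidate documents
  for the contiguous token sequence (exact, not estimated).
- The sentence splitter treats newlines as hard boundaries; the title is
  sentence 0. A period ends a sentence only before whitespace and a
  non-lowercase character, with a dotted-abbreviation guard list
  (`et al.`, `Fig.`, `i.e.`, …).
- Serialization is canonical (no internal whitespace); `MESHD` is
  normalized to `MESH` at entity construction since both spellings occur
  in curated data.
- Unknown function tokens parse as generic functions: the five classical
  BEL function categories are lexicon labels, not grammar restrictions,
  so unseen test vocabulary still parses.
- Degenerate inputs: empty corpora retrieve nothing; statements whose
  entities never co-occur return an empty evidence list; an empty result
  set has precision 0 (with a warning); the classifier refuses
  single-class training data and predicts the majority prior for
  feature-less sentences.
- Evidence sentences are not deduplicated across abstract and full-text
  versions of the same article.
- Function/argument trigger groups are included in the retrieval query
  as optional clauses and always used again at ranking time; a flag
  (`include_function_groups=False`) restricts retrieval to entities
  only.

## Known limitations

- The trigger dictionaries shipped are small expert-seeded defaults; any
  serious use should supply domain lexicons via the TSV interfaces.
- Grammar coverage is the statement subset used in curation tasks
  (functions over entities, `pmod`, nested statements as objects), not
  the full BEL 2.0 language (no translocations, reactions, or document
  headers).
- The in-process index holds postings and token streams in memory; it is
  meant for corpora up to, say, 10^5 documents, not the full PubMed.
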