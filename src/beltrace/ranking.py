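"""Detect BEL elements in sentences, filter, score, and rank evidence.

A sentence is evidence for a statement only if it mentions *every*
statement entity, either by the exact name or by a synonym (the
mandatory-entity filter).  Surviving sentences are scored by summing a
weight per distinct matched element, with a strict preference hierarchy:

    exact entity > entity synonym >= modification argument
    > function trigger > relation trigger

plus a bonus when the polarity classifier agrees with the statement's
relation.  The defaults (16/12/8/4/2, bonus 2) encode the hierarchy;
the hierarchy, not the numbers, is the contract, and all weights are
configurable.  Modification cues — the modification-type word
("phosphorylation"), the residue word ("serine") and the literal
sequence position ("520") — are all modification-argument matches: a
sentence naming the exact position is extremely strong evidence.

At most ``k`` (default 10) candidates are returned per statement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .classifier import RelationClassifier
from .corpus import Index, Sentence, doc_sentences, retrieve_citations
from .lexicons import (
    EntityLexicon,
    TriggerLexicon,
    default_trigger_lexicon,
    entity_synonyms,
    function_triggers,
    relation_triggers,
)
from .model import (
    BELStatement,
    collect_entities,
    collect_functions,
    relation_polarity,
)
from .query import TranslatedQuery, translate_statement

__all__ = [
    "ElementMatch",
    "RankWeights",
    "EvidenceCandidate",
    "detect_elements",
    "entity_filter",
    "score_sentence",
    "rank_evidence",
]


@dataclass(frozen=True)
class ElementMatch:
    kind: str  # entity_exact | entity_synonym | function_arg | function | relation
    key: str  # the BEL element matched, e.g. "HGNC:HSF1", "mod:P", "pos:520"
    surface: str  # the matched text span
    weight: float


@dataclass(frozen=True)
class RankWeights:
    """Per-kind match weights plus the classifier agreement bonus.

    Must satisfy ``entity_exact > entity_synonym >= function_arg >
    function > relation``.
    """

    entity_exact: float = 16.0
    entity_synonym: float = 12.0
    function_arg: float = 8.0
    function: float = 4.0
    relation: float = 2.0
    classifier_bonus: float = 2.0

    def __post_init__(self):
        ok = (
            self.entity_exact > self.entity_synonym >= self.function_arg
            > self.function > self.relation > 0
        )
        if not ok:
            raise ValueError("weights must respect the element hierarchy")

    def of(self, kind: str) -> float:
        return getattr(self, kind)


def _surface_pattern(surface: str) -> re.Pattern:
    """Case-insensitive word-boundary pattern; whitespace/hyphen runs in
    multi-word surfaces match any such run in text."""
    parts = [re.escape(p) for p in re.split(r"[\s\-]+", surface.strip()) if p]
    return re.compile(r"(?<!\w)" + r"[\s\-]+".join(parts) + r"(?!\w)", re.IGNORECASE)


def _find(surfaces: list[str], text: str) -> str | None:
    """First surface (longest first) that matches in text, as matched."""
    for surface in sorted(surfaces, key=len, reverse=True):
        m = _surface_pattern(surface).search(text)
        if m:
            return m.group(0)
    return None


def detect_elements(
    sentence_text: str,
    stmt: BELStatement,
    entity_lex: EntityLexicon | None = None,
    trigger_lex: TriggerLexicon | None = None,
    weights: RankWeights = RankWeights(),
) -> list[ElementMatch]:
    """Dictionary-based scan of one sentence for the statement's elements.

    Case-insensitive, word-boundary, longest-match; at most one match per
    (kind, key) — presence, not count, is what scores.
    """
    entity_lex = entity_lex if entity_lex is not None else EntityLexicon()
    trigger_lex = trigger_lex if trigger_lex is not None else default_trigger_lexicon()
    matches: list[ElementMatch] = []

    for ent in collect_entities(stmt):
        exact = _find([ent.name], sentence_text)
        if exact is not None:
            matches.append(
                ElementMatch("entity_exact", str(ent), exact, weights.entity_exact)
            )
            continue
        syn = _find(entity_synonyms(entity_lex, ent), sentence_text)
        if syn is not None:
            matches.append(
                ElementMatch("entity_synonym", str(ent), syn, weights.entity_synonym)
            )

    seen: set[tuple[str, str]] = set()

    def add(kind: str, key: str, surfaces: list[str]) -> None:
        if (kind, key) in seen or not surfaces:
            return
        hit = _find(surfaces, sentence_text)
        if hit is not None:
            seen.add((kind, key))
            matches.append(ElementMatch(kind, key, hit, weights.of(kind)))

    for func, modspec in collect_functions(stmt):
        if modspec is None:
            add("function", f"fn:{func}", function_triggers(trigger_lex, func))
        else:
            add("function", "fn:pmod", function_triggers(trigger_lex, "pmod"))
            add("function_arg", f"mod:{modspec.mod_type}",
                function_triggers(trigger_lex, modspec.mod_type))
            if modspec.residue is not None:
                add("function_arg", f"residue:{modspec.residue}",
                    function_triggers(trigger_lex, modspec.residue))
            if modspec.position is not None:
                add("function_arg", f"pos:{modspec.position}", [str(modspec.position)])

    polarity = relation_polarity(stmt.relation)
    add("relation", polarity, relation_triggers(trigger_lex, polarity))
    return matches


def entity_filter(matches: list[ElementMatch], stmt: BELStatement) -> bool:
    """True iff every statement entity is matched exactly or by synonym."""
    covered = {
        m.key for m in matches if m.kind in ("entity_exact", "entity_synonym")
    }
    return all(str(ent) in covered for ent in collect_entities(stmt))


def score_sentence(
    matches: list[ElementMatch],
    weights: RankWeights = RankWeights(),
    classifier_agrees: bool = False,
) -> float:
    """Sum of match weights plus the agreement bonus (no disagreement
    penalty: the classifier can support but never veto lexical evidence)."""
    score = sum(weights.of(m.kind) for m in matches)
    if classifier_agrees:
        score += weights.classifier_bonus
    return score


@dataclass(frozen=True)
class EvidenceCandidate:
    sentence: Sentence
    matches: tuple[ElementMatch, ...]
    lexical_score: float
    classifier_agrees: bool
    final_score: float
    rank: int
    retrieval_score: float = 0.0


def rank_evidence(
    stmt: BELStatement,
    index: Index,
    entity_lex: EntityLexicon | None = None,
    trigger_lex: TriggerLexicon | None = None,
    classifier: RelationClassifier | None = None,
    k: int = 10,
    cap_per_source: int = 1000,
    weights: RankWeights = RankWeights(),
    query: TranslatedQuery | None = None,
) -> list[EvidenceCandidate]:
    """Full ranking pass for one statement.

    Retrieves citations (per-source cap), splits them into sentences,
    detects elements, applies the mandatory-entity filter, scores, and
    returns at most ``k`` candidates ordered by final score (ties broken
    by citation retrieval score, then doc_id, then sentence index).
    Without a classifier the agreement bonus is simply skipped.
    """
    entity_lex = entity_lex if entity_lex is not None else EntityLexicon()
    trigger_lex = trigger_lex if trigger_lex is not None else default_trigger_lexicon()
    if query is None:
        query = translate_statement(stmt, entity_lex, trigger_lex)
    citations = retrieve_citations(index, query, cap_per_source)
    polarity = relation_polarity(stmt.relation)

    scored: list[EvidenceCandidate] = []
    for doc_id, retrieval_score in citations:
        for sent in doc_sentences(index.documents[doc_id]):
            matches = detect_elements(sent.text, stmt, entity_lex, trigger_lex, weights)
            if not entity_filter(matches, stmt):
                continue
            agrees = False
            if classifier is not None:
                spans = _entity_spans(sent.text, matches)
                predicted, _ = classifier.predict_with_confidence((sent.text, spans))
                agrees = predicted == polarity
            lexical = score_sentence(matches, weights, classifier_agrees=False)
            final = score_sentence(matches, weights, classifier_agrees=agrees)
            scored.append(
                EvidenceCandidate(
                    sent, tuple(matches), lexical, agrees, final, 0, retrieval_score
                )
            )

    scored.sort(
        key=lambda c: (
            -c.final_score,
            -c.retrieval_score,
            c.sentence.doc_id,
            c.sentence.sent_index,
        )
    )
    return [
        EvidenceCandidate(
            c.sentence, c.matches, c.lexical_score, c.classifier_agrees,
            c.final_score, rank, c.retrieval_score,
        )
        for rank, c in enumerate(scored[:k], start=1)
    ]


def _entity_spans(text: str, matches: list[ElementMatch]) -> tuple[tuple[int, int], ...]:
    """Character spans of the matched entity surfaces, for the classifier."""
    spans: list[tuple[int, int]] = []
    taken: set[tuple[int, int]] = set()
    for m in matches:
        if m.kind not in ("entity_exact", "entity_synonym"):
            continue
        hit = _surface_pattern(m.surface).search(text)
        if hit and (hit.start(), hit.end()) not in taken:
            taken.add((hit.start(), hit.end()))
            spans.append((hit.start(), hit.end()))
    # drop overlaps, keeping earlier spans
    spans.sort()
    out: list[tuple[int, int]] = []
    prev_end = -1
    for s, e in spans:
        if s >= prev_end:
            out.append((s, e))
            prev_end = e
    return tuple(out)
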