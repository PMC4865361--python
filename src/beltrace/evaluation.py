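"""Precision, average precision, MAP baselines, and stratified reports.

Evaluation follows the ranked-retrieval conventions of the curation
task: each returned sentence is a true positive (TP) or false positive
(FP) under a relevance criterion ("full": the sentence supports the
complete statement; "context": it at least mentions all entities in a
relevant setting), precision is TP/(TP+FP) over all returned sentences,
and ranking quality is mean average precision (MAP) bracketed by three
baselines computed on the same label multiset per query:

* worst  — every TP ranked after every FP,
* random — mean MAP over uniformly reshuffled lists (2000 by default),
* best   — every TP ranked before every FP.

The average-precision denominator is the number of TPs *retrieved*, not
all relevant sentences in existence: only returned sentences carry
relevance judgments, so recall-normalised AP is not computable.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .model import BELStatement, collect_entities

__all__ = [
    "RankedRun",
    "CriterionReport",
    "EvalReport",
    "precision_from_counts",
    "average_precision",
    "mean_average_precision",
    "map_baselines",
    "evaluate_run",
    "labels_for_criterion",
]

log = logging.getLogger(__name__)

#: per query_id: ordered binary labels (True = TP under some criterion)
RankedRun = dict[str, list[bool]]


def precision_from_counts(tp: int, fp: int) -> float:
    """``TP / (TP + FP)``; 0 with a warning when nothing was returned."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        log.warning("precision of an empty result set reported as 0")
        return 0.0
    return tp / (tp + fp)


def average_precision(labels) -> float:
    """AP of one ranked TP/FP list.

    Mean over TP positions i (1-based) of precision@i; the denominator is
    the number of TPs in the list.  Empty or all-FP lists score 0.
    """
    labels = list(labels)
    hits = 0
    total = 0.0
    for i, is_tp in enumerate(labels, start=1):
        if is_tp:
            hits += 1
            total += hits / i
    return total / hits if hits else 0.0


def mean_average_precision(run: RankedRun) -> float:
    if not run:
        return 0.0
    return sum(average_precision(v) for v in run.values()) / len(run)


def map_baselines(
    run: RankedRun,
    mode: str,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> float:
    """MAP of the worst / random / best reordering of each query's labels.

    ``random`` reshuffles every query's list independently ``n_shuffles``
    times and averages the per-shuffle MAP.
    """
    if mode == "worst":
        return mean_average_precision(
            {q: sorted(v) for q, v in run.items()}  # False before True
        )
    if mode == "best":
        return mean_average_precision(
            {q: sorted(v, reverse=True) for q, v in run.items()}
        )
    if mode == "random":
        if not run:
            return 0.0
        rng = random.Random(seed)
        shuffled = {q: list(v) for q, v in run.items()}
        total = 0.0
        for _ in range(n_shuffles):
            for v in shuffled.values():
                rng.shuffle(v)
            total += mean_average_precision(shuffled)
        return total / n_shuffles
    raise ValueError(f"unknown baseline mode {mode!r}")


# ---------------------------------------------------------------------------
# Full reports

@dataclass
class CriterionReport:
    criterion: str
    tp: int
    fp: int
    precision: float
    per_query_ap: dict[str, float]
    map: float
    map_worst: float
    map_random: float
    map_best: float


@dataclass
class EvalReport:
    criteria: dict[str, CriterionReport]
    n_queries: int
    n_sentences: int
    mean_sentences_per_query: float
    #: namespace -> (n queries with >=1 full-relevant sentence, n without,
    #: pct with, pct without); percentages are rounded integers
    namespace_breakdown: dict[str, tuple[int, int, int, int]] = field(
        default_factory=dict
    )


def _gold_mapping(gold) -> dict[tuple[str, str, int], str]:
    """Accept a list of GoldLabel-like records or a prepared dict."""
    if isinstance(gold, dict):
        return gold
    return {(g.query_id, g.doc_id, g.sent_index): g.relevance for g in gold}


#: relevance labels counted as TP under each criterion
_CRITERIA = {
    "full": {"full"},
    "relaxed": {"full", "relaxed"},
    "context": {"full", "relaxed", "context"},
}


def labels_for_criterion(run, gold, criterion: str) -> RankedRun:
    """Binary TP/FP labels for each query's ranked (doc_id, sent_index)
    list under a relevance criterion."""
    mapping = _gold_mapping(gold)
    relevant = _CRITERIA[criterion]
    gold_queries = {q for q, _, _ in mapping}
    out: RankedRun = {}
    for qid, ranked in run.items():
        if qid not in gold_queries:
            raise KeyError(f"query {qid!r} absent from the gold standard")
        out[qid] = [
            mapping.get((qid, doc_id, sent_index), "irrelevant") in relevant
            for doc_id, sent_index in ranked
        ]
    return out


def evaluate_run(
    run: dict[str, list[tuple[str, int]]],
    gold,
    statements: dict[str, BELStatement] | None = None,
    n_shuffles: int = 2000,
    seed: int = 0,
    criteria=("full", "context"),
) -> EvalReport:
    """Score a ranked run against gold labels.

    ``run`` maps query_id to the ordered returned (doc_id, sent_index)
    pairs; ``gold`` supplies per-sentence relevance (full / relaxed /
    context; anything unlabeled is irrelevant).  When ``statements`` is
    given, queries are additionally stratified by entity namespace into
    groups with and without at least one full-relevant returned sentence.
    """
    mapping = _gold_mapping(gold)
    reports: dict[str, CriterionReport] = {}
    for criterion in criteria:
        labeled = labels_for_criterion(run, mapping, criterion)
        tp = sum(sum(v) for v in labeled.values())
        fp = sum(len(v) - sum(v) for v in labeled.values())
        reports[criterion] = CriterionReport(
            criterion=criterion,
            tp=tp,
            fp=fp,
            precision=precision_from_counts(tp, fp),
            per_query_ap={q: average_precision(v) for q, v in labeled.items()},
            map=mean_average_precision(labeled),
            map_worst=map_baselines(labeled, "worst"),
            map_random=map_baselines(labeled, "random", n_shuffles, seed),
            map_best=map_baselines(labeled, "best"),
        )

    n_queries = len(run)
    n_sentences = sum(len(v) for v in run.values())
    mean_sents = n_sentences / n_queries if n_queries else 0.0

    breakdown: dict[str, tuple[int, int, int, int]] = {}
    if statements is not None and "full" in reports:
        full_labels = labels_for_criterion(run, mapping, "full")
        for qid in run:
            stmt = statements.get(qid)
            if stmt is None:
                raise KeyError(f"no statement for query {qid!r}")
            has_evidence = any(full_labels[qid])
            for ns in {e.namespace for e in collect_entities(stmt)}:
                prev = breakdown.get(ns, (0, 0, 0, 0))
                breakdown[ns] = (
                    prev[0] + (1 if has_evidence else 0),
                    prev[1] + (0 if has_evidence else 1),
                    0,
                    0,
                )
        for ns, (a, b, _, _) in breakdown.items():
            total = a + b
            breakdown[ns] = (a, b, round(100 * a / total), round(100 * b / total))

    return EvalReport(
        criteria=reports,
        n_queries=n_queries,
        n_sentences=n_sentences,
        mean_sentences_per_query=mean_sents,
        namespace_breakdown=breakdown,
    )
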