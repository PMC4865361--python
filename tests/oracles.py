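"""Single-purpose reference implementations used only to cross-check the
package; they recompute everything directly from raw inputs and share no
code with the implementation under test."""

from __future__ import annotations

import math
import re
from itertools import permutations


def _tokens(text: str) -> list[str]:
    return re.findall(r"[a-z0-9]+", text.lower())


def _count_contiguous(needle: list[str], haystack: list[str]) -> int:
    k = len(needle)
    if k == 0 or k > len(haystack):
        return 0
    return sum(1 for i in range(len(haystack) - k + 1) if haystack[i:i + k] == needle)


def brute_force_retrieve(docs, query, cap_per_source=1000, k1=1.2, b=0.75):
    """Score every document directly from raw text: boolean required-group
    filter, weighted BM25 sum, sort, per-source cap, abstracts first."""
    doc_tokens = {d.doc_id: _tokens(d.title + "\n" + d.body) for d in docs}
    n = len(docs)
    if n == 0:
        return []
    avgdl = sum(len(t) for t in doc_tokens.values()) / n

    def tf(surface, doc_id):
        return _count_contiguous(_tokens(surface), doc_tokens[doc_id])

    def df(surface):
        return sum(1 for d in docs if tf(surface, d.doc_id) > 0)

    def score(doc_id):
        total = 0.0
        dl = len(doc_tokens[doc_id])
        for group in query.groups:
            for term in group.terms:
                f = tf(term.surface, doc_id)
                if f == 0:
                    continue
                d = df(term.surface)
                idf = math.log(1.0 + (n - d + 0.5) / (d + 0.5))
                total += term.weight * idf * f * (k1 + 1.0) / (
                    f + k1 * (1.0 - b + b * dl / avgdl)
                )
        return total

    kept = [
        d for d in docs
        if all(
            any(tf(t.surface, d.doc_id) > 0 for t in g.terms)
            for g in query.groups
            if g.required
        )
    ]
    ranked = sorted(((d.doc_id, score(d.doc_id)) for d in kept),
                    key=lambda x: (-x[1], x[0]))
    sources = {d.doc_id: d.source for d in docs}
    abstracts = [r for r in ranked if sources[r[0]] == "abstract"][:cap_per_source]
    fulltexts = [r for r in ranked if sources[r[0]] != "abstract"][:cap_per_source]
    return abstracts + fulltexts


def ap_first_principles(labels) -> float:
    """Average precision recomputed by slicing at each relevant rank."""
    labels = list(labels)
    positions = [i for i, tp in enumerate(labels, start=1) if tp]
    if not positions:
        return 0.0
    return sum(sum(labels[:i]) / i for i in positions) / len(positions)


def exhaustive_permutation_ap(labels):
    """(min, mean, max) AP over all distinct permutations of the labels."""
    labels = tuple(labels)
    seen = set(permutations(labels))
    values = [ap_first_principles(p) for p in seen]
    return min(values), sum(values) / len(values), max(values)
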