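"""Corpus readers, sentence splitting, and boosted-BM25 retrieval.

Documents (PubMed/MEDLINE XML abstracts or a JSONL dialect for
full-text-like records) are indexed whole into an in-process inverted
index.  A translated query retrieves at most ``cap_per_source`` citations
per source (abstracts, then full texts), keeping only documents that
satisfy every required clause group; ranking within the candidate set is
boost-weighted Okapi BM25:

    score(d) = sum_t  w_t * idf(t) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * |d|/avgdl))

with ``k1 = 1.2``, ``b = 0.75`` and ``idf = ln(1 + (N - df + 0.5)/(df + 0.5))``.
Multi-word query terms are scored as phrases: their tf is the number of
contiguous occurrences of the token sequence.

Sentence splitting is rule-based (sentence punctuation plus an
abbreviation guard list) and offset-preserving: each sentence records
half-open character offsets into ``title + "\\n" + body``.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

from lxml import etree

from .query import TranslatedQuery

__all__ = [
    "Document",
    "Sentence",
    "Index",
    "read_pubmed_xml",
    "read_jsonl_corpus",
    "split_sentences",
    "doc_sentences",
    "tokenize",
    "build_index",
    "score_document",
    "retrieve_citations",
    "save_index",
    "load_index",
]

log = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1

BM25_K1 = 1.2
BM25_B = 0.75


@dataclass(frozen=True)
class Document:
    doc_id: str
    source: str  # "abstract" | "fulltext"
    title: str
    body: str

    def __post_init__(self):
        if not self.body and not self.title:
            raise ValueError(f"document {self.doc_id}: empty title and body")

    @property
    def text(self) -> str:
        return f"{self.title}\n{self.body}"


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    sent_index: int
    text: str
    char_start: int
    char_end: int


# ---------------------------------------------------------------------------
# Readers

def read_pubmed_xml(path) -> list[Document]:
    """Read PubmedArticle records from a MEDLINE/PubMed XML file.

    Each record yields one abstract Document; structured abstracts
    (multiple AbstractText segments) are joined with single spaces.
    Records lacking a PMID are skipped with a warning.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed PubMed XML in {path}: {e}") from e
    docs: list[Document] = []
    for i, rec in enumerate(tree.iter("PubmedArticle")):
        pmid_el = rec.find(".//MedlineCitation/PMID")
        if pmid_el is None:
            pmid_el = rec.find(".//PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            log.warning("record %d lacks a PMID; skipped", i)
            continue
        title_el = rec.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        segments = [
            " ".join("".join(el.itertext()).split())
            for el in rec.findall(".//Abstract/AbstractText")
        ]
        body = " ".join(s for s in segments if s)
        docs.append(Document(pmid, "abstract", title, body))
    return docs


def read_jsonl_corpus(path) -> list[Document]:
    """Read a JSONL corpus: one object per line with keys ``id``,
    ``source`` (defaults to ``abstract``), ``title``, ``text``."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: bad JSON: {e}") from e
            doc_id = str(rec["id"])
            if doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate document id {doc_id!r}")
            seen.add(doc_id)
            docs.append(
                Document(
                    doc_id,
                    rec.get("source", "abstract"),
                    rec.get("title", ""),
                    rec.get("text", ""),
                )
            )
    return docs


# ---------------------------------------------------------------------------
# Sentence splitting

#: Dotted tokens that do not end a sentence.  Compared lowercase against
#: the letters-and-dots run preceding a period; single letters (initials)
#: are guarded separately.
_ABBREVIATIONS = frozenset({
    "al", "fig", "figs", "eq", "eqs", "ref", "refs", "i.e", "e.g", "cf",
    "vs", "ca", "approx", "dr", "st", "no", "etc.al",
})

_WORD_BEFORE = re.compile(r"[A-Za-z.]+$")


def _is_abbreviation(text: str, dot: int) -> bool:
    m = _WORD_BEFORE.search(text, 0, dot)
    if not m:
        return False
    word = m.group(0).rstrip(".")
    return word.lower() in _ABBREVIATIONS


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans ``(char_start, char_end)``.

    Boundaries are sentence punctuation followed by whitespace and a
    non-lowercase character, hard newlines, and end of text; an
    abbreviation guard list keeps "et al.", "Fig. 2", "i.e." intact.
    Spans are trimmed of surrounding whitespace, so they partition the
    text modulo inter-sentence whitespace.
    """
    n = len(text)
    raw: list[tuple[int, int]] = []
    start = 0
    i = 0
    while i < n:
        c = text[i]
        if c == "\n":
            raw.append((start, i))
            start = i + 1
            i += 1
            continue
        if c in ".!?":
            end = i + 1
            j = end
            while j < n and text[j] in " \t":
                j += 1
            at_eot = j >= n
            next_ok = at_eot or text[j] == "\n" or not text[j].islower()
            has_gap = j > end or at_eot
            if next_ok and has_gap and not (c == "." and _is_abbreviation(text, i)):
                raw.append((start, end))
                start = j
                i = j
                continue
        i += 1
    if start < n:
        raw.append((start, n))
    spans: list[tuple[int, int]] = []
    for s, e in raw:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append((s, e))
    return spans


def doc_sentences(doc: Document) -> list[Sentence]:
    """Sentences of a document over ``title + "\\n" + body`` with stable
    offsets; the title, when present, is sentence 0."""
    text = doc.text
    return [
        Sentence(doc.doc_id, i, text[s:e], s, e)
        for i, (s, e) in enumerate(split_sentences(text))
    ]


# ---------------------------------------------------------------------------
# Indexing

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase tokens: maximal runs of letters and digits."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Index:
    """In-process inverted index over whole documents."""

    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_lengths: dict[str, int] = field(default_factory=dict)
    doc_tokens: dict[str, list[str]] = field(default_factory=dict)
    documents: dict[str, Document] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    @property
    def avg_doc_length(self) -> float:
        if not self.doc_lengths:
            return 0.0
        return sum(self.doc_lengths.values()) / len(self.doc_lengths)

    # -- term statistics ----------------------------------------------------

    def _phrase_tf(self, tokens: list[str], doc_id: str) -> int:
        doc = self.doc_tokens[doc_id]
        k = len(tokens)
        if k == 0 or k > len(doc):
            return 0
        return sum(1 for i in range(len(doc) - k + 1) if doc[i:i + k] == tokens)

    def term_tf(self, surface: str, doc_id: str) -> int:
        """Occurrences of a (possibly multi-word) query term in a document;
        phrases count contiguous token-sequence occurrences."""
        tokens = tokenize(surface)
        if not tokens:
            return 0
        if len(tokens) == 1:
            return self.postings.get(tokens[0], {}).get(doc_id, 0)
        return self._phrase_tf(tokens, doc_id)

    def term_df(self, surface: str) -> int:
        tokens = tokenize(surface)
        if not tokens:
            return 0
        if len(tokens) == 1:
            return len(self.postings.get(tokens[0], {}))
        # candidate docs must contain the rarest token of the phrase
        rarest = min(tokens, key=lambda t: len(self.postings.get(t, {})))
        return sum(
            1
            for doc_id in self.postings.get(rarest, {})
            if self._phrase_tf(tokens, doc_id) > 0
        )

    def docs_with_term(self, surface: str) -> set[str]:
        tokens = tokenize(surface)
        if not tokens:
            return set()
        if len(tokens) == 1:
            return set(self.postings.get(tokens[0], {}))
        rarest = min(tokens, key=lambda t: len(self.postings.get(t, {})))
        return {
            doc_id
            for doc_id in self.postings.get(rarest, {})
            if self._phrase_tf(tokens, doc_id) > 0
        }


def build_index(docs: list[Document]) -> Index:
    """Index documents whole (title + body) under lowercase tokenization."""
    idx = Index()
    for doc in docs:
        if doc.doc_id in idx.documents:
            raise ValueError(f"duplicate document id {doc.doc_id!r}")
        tokens = tokenize(doc.text)
        idx.documents[doc.doc_id] = doc
        idx.sources[doc.doc_id] = doc.source
        idx.doc_lengths[doc.doc_id] = len(tokens)
        idx.doc_tokens[doc.doc_id] = tokens
        for tok in tokens:
            bucket = idx.postings.setdefault(tok, {})
            bucket[doc.doc_id] = bucket.get(doc.doc_id, 0) + 1
    return idx


# ---------------------------------------------------------------------------
# Scoring and retrieval

def _bm25_term(idx: Index, tf: int, df: int, doc_len: int, k1: float, b: float) -> float:
    if tf == 0 or df == 0:
        return 0.0
    idf = math.log(1.0 + (idx.n_docs - df + 0.5) / (df + 0.5))
    denom = tf + k1 * (1.0 - b + b * doc_len / idx.avg_doc_length)
    return idf * tf * (k1 + 1.0) / denom


def score_document(
    idx: Index,
    query: TranslatedQuery,
    doc_id: str,
    *,
    k1: float = BM25_K1,
    b: float = BM25_B,
) -> float:
    """Boost-weighted BM25 score of one document: each query term
    contributes ``weight * BM25(term, doc)``; zero iff no term occurs."""
    if doc_id not in idx.doc_lengths:
        raise KeyError(f"unknown document id {doc_id!r}")
    doc_len = idx.doc_lengths[doc_id]
    score = 0.0
    for group in query.groups:
        for term in group.terms:
            tf = idx.term_tf(term.surface, doc_id)
            if tf == 0:
                continue
            df = idx.term_df(term.surface)
            score += term.weight * _bm25_term(idx, tf, df, doc_len, k1, b)
    return score


def retrieve_citations(
    idx: Index,
    query: TranslatedQuery,
    cap_per_source: int = 1000,
    *,
    k1: float = BM25_K1,
    b: float = BM25_B,
) -> list[tuple[str, float]]:
    """Retrieve citations for a translated query.

    Only documents containing at least one term of every required clause
    group are candidates.  Candidates are scored with boosted BM25 and
    sorted by score descending (ties by doc_id ascending); at most
    ``cap_per_source`` survive per source, abstracts concatenated before
    full texts.
    """
    if idx.n_docs == 0:
        return []
    candidates: set[str] | None = None
    for group in query.required_groups():
        matched: set[str] = set()
        for term in group.terms:
            matched |= idx.docs_with_term(term.surface)
        candidates = matched if candidates is None else candidates & matched
        if not candidates:
            return []
    assert candidates is not None
    scored = sorted(
        ((doc_id, score_document(idx, query, doc_id, k1=k1, b=b)) for doc_id in candidates),
        key=lambda x: (-x[1], x[0]),
    )
    by_source: dict[str, list[tuple[str, float]]] = {"abstract": [], "fulltext": []}
    for doc_id, s in scored:
        src = idx.sources.get(doc_id, "abstract")
        bucket = by_source.setdefault(src, [])
        if len(bucket) < cap_per_source:
            bucket.append((doc_id, s))
    out = list(by_source["abstract"])
    for src, bucket in by_source.items():
        if src != "abstract":
            out.extend(bucket)
    return out


# ---------------------------------------------------------------------------
# Persistence

def save_index(idx: Index, path) -> None:
    """Persist as versioned JSON (documents + config); postings are
    rebuilt deterministically on load."""
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "documents": [
            {"id": d.doc_id, "source": d.source, "title": d.title, "text": d.body}
            for d in idx.documents.values()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_index(path) -> Index:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {version!r}")
    docs = [
        Document(r["id"], r.get("source", "abstract"), r.get("title", ""), r.get("text", ""))
        for r in payload["documents"]
    ]
    return build_index(docs)
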