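"""Synthetic corpora with planted evidence, for end-to-end testing.

Real evidence retrieval needs a PubMed-scale index and manually judged
relevance, neither of which fits in a test suite.  This generator builds
the same *structure* at desk scale: for each invented BEL statement it
plants "full" evidence sentences (every statement entity, by name or
synonym, co-occurring with a correct-polarity trigger and optionally
modification cues), "context" sentences (all entities but a wrong or
missing trigger), and distractor documents that mention at most one of
the entities and therefore can never satisfy the mandatory-entity
filter.  All vocabulary is synthetic (pseudo-words; gene names like
``GENAB``) and checked against the built-in trigger dictionary, so
separability is under experimental control rather than accident.

A companion generator emits balanced increase/decrease sentences for
classifier training, with a ``trigger_overlap`` dial that degrades class
separability from perfect (0.0) to chance (1.0).

Everything is deterministic given the mandatory seed.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass

from .corpus import Document, doc_sentences
from .classifier import LabeledSentence
from .lexicons import EntityLexicon, _DEFAULT_TRIGGERS
from .model import BELStatement, parse_statement

__all__ = ["GeneratorParams", "GoldLabel", "SyntheticCorpus",
           "generate_corpus", "generate_relation_dataset"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic study.

    Defaults are the conditions the test suite runs under: 50 statements,
    3 planted full + 2 context sentences each, 50 distractor documents,
    2 synonyms per entity, 8 trigger words per polarity class, sentences
    of 8-16 noise tokens, classifier data of 400 balanced sentences with
    fully disjoint class vocabularies (overlap 0).
    """

    seed: int
    n_statements: int = 50
    n_planted_per_statement: int = 3
    n_context_per_statement: int = 2
    n_distractor_docs: int = 50
    synonym_count: int = 2
    trigger_vocab_size: int = 8
    sentence_length: tuple[int, int] = (8, 16)
    n_relation_sentences: int = 400
    trigger_overlap: float = 0.0
    max_total_docs: int | None = None

    def __post_init__(self):
        counts = (
            self.n_statements, self.n_planted_per_statement,
            self.n_context_per_statement, self.n_distractor_docs,
            self.synonym_count, self.trigger_vocab_size,
            self.n_relation_sentences,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all generator counts must be >= 0")
        if not 0.0 <= self.trigger_overlap <= 1.0:
            raise ValueError("trigger_overlap must be in [0, 1]")
        lo, hi = self.sentence_length
        if lo < 1 or hi < lo:
            raise ValueError("sentence_length must be a nondecreasing range >= 1")
        needed = self.n_statements * (
            self.n_planted_per_statement + self.n_context_per_statement
        ) + self.n_distractor_docs
        if self.max_total_docs is not None and needed > self.max_total_docs:
            raise ValueError(
                f"params need {needed} documents but max_total_docs="
                f"{self.max_total_docs}"
            )


@dataclass(frozen=True)
class GoldLabel:
    query_id: str
    doc_id: str
    sent_index: int
    relevance: str  # full | context | irrelevant


@dataclass
class SyntheticCorpus:
    statements: dict[str, BELStatement]
    documents: list[Document]
    entity_lexicon: EntityLexicon
    gold: list[GoldLabel]


# ---------------------------------------------------------------------------
# Vocabulary construction

_SYLLABLES = [c + v for c in "bdfglmnprstvz" for v in "aeiou"]

#: tokens that must never appear as noise (every built-in trigger token,
#: plus the synonym template words)
_BANNED_NOISE = {
    tok
    for triggers in _DEFAULT_TRIGGERS.values()
    for t in triggers
    for tok in t.split()
} | {"protein", "factor", "gen"}


def _noise_vocabulary(rng: random.Random, size: int = 250) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 4)))
        # "gen"-prefixed pseudo-words could collide with invented gene names
        if word not in seen and word not in _BANNED_NOISE and not word.startswith("gen"):
            seen.add(word)
            vocab.append(word)
    return vocab


def _alpha_id(i: int) -> str:
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def _sentence(rng: random.Random, noise: list[str], insertions: list[str],
              length: tuple[int, int]) -> str:
    """Noise tokens with the insertion strings spliced in at random
    interior positions, in order; capitalized, terminated with '.'."""
    n = max(rng.randint(*length), len(insertions))
    tokens = [rng.choice(noise) for _ in range(n)]
    positions = sorted(rng.sample(range(1, n + 1), len(insertions)))
    for offset, (pos, ins) in enumerate(zip(positions, insertions)):
        tokens.insert(pos + offset, ins)
    text = " ".join(tokens)
    return text[0].upper() + text[1:] + "."


# ---------------------------------------------------------------------------
# Corpus generation

def generate_corpus(params: GeneratorParams) -> SyntheticCorpus:
    """Statements, documents, entity lexicon and gold labels.

    Every planted "full" sentence passes the mandatory-entity filter for
    its statement by construction; no distractor document can satisfy
    all required query groups of any statement.
    """
    rng = random.Random(params.seed)
    noise = _noise_vocabulary(rng)
    lexicon = EntityLexicon()
    statements: dict[str, BELStatement] = {}
    documents: list[Document] = []
    gold: list[GoldLabel] = []

    inc_triggers = list(_DEFAULT_TRIGGERS["increase"][: params.trigger_vocab_size])
    dec_triggers = list(_DEFAULT_TRIGGERS["decrease"][: params.trigger_vocab_size])

    entity_surfaces: dict[str, list[str]] = {}  # name -> [name] + synonyms

    def invent_entity(k: int) -> tuple[str, str]:
        ns = rng.choice(["HGNC", "MGI"])
        name = f"GEN{_alpha_id(k)}"
        surfaces = [name]
        for j in range(params.synonym_count):
            syn = f"{name.lower()} factor {j + 1}"
            lexicon.add(ns, name, syn)
            surfaces.append(syn)
        entity_surfaces[name] = surfaces
        return ns, name

    residues = {"S": "serine", "T": "threonine", "Y": "tyrosine"}

    for i in range(params.n_statements):
        qid = f"Q{i:03d}"
        ns1, name1 = invent_entity(2 * i)
        ns2, name2 = invent_entity(2 * i + 1)
        relation = rng.choice(
            ["increases", "decreases", "directly increases", "directly decreases"]
        )
        polarity = "increase" if "increase" in relation else "decrease"
        modspec = None
        obj = f"p({ns2}:{name2})"
        if rng.random() < 0.5:
            residue = rng.choice(list(residues))
            position = rng.randint(50, 999)
            modspec = (residue, position)
            obj = f"p({ns2}:{name2},pmod(P,{residue},{position}))"
        subj = f"p({ns1}:{name1})"
        if rng.random() < 0.3:
            subj = f"kin({subj})"
        stmt = parse_statement(f"{subj} {relation} {obj}")
        statements[qid] = stmt

        right = inc_triggers if polarity == "increase" else dec_triggers
        wrong = dec_triggers if polarity == "increase" else inc_triggers

        def surface(name: str) -> str:
            return rng.choice(entity_surfaces[name])

        for j in range(params.n_planted_per_statement):
            parts = [surface(name1), rng.choice(right), surface(name2)]
            if modspec is not None and rng.random() < 0.7:
                residue, position = modspec
                parts += ["phosphorylation", residues[residue], str(position)]
            body = _sentence(rng, noise, parts, params.sentence_length)
            doc_id = f"D{i:03d}F{j}"
            source = rng.choice(["abstract", "fulltext"])
            title = " ".join(rng.choice(noise) for _ in range(3)).capitalize()
            doc = Document(doc_id, source, title, body)
            documents.append(doc)
            sent_index = _planted_sent_index(doc, body)
            gold.append(GoldLabel(qid, doc_id, sent_index, "full"))

        for j in range(params.n_context_per_statement):
            parts = [surface(name1), surface(name2)]
            if rng.random() < 0.5:
                parts.insert(1, rng.choice(wrong))
            body = _sentence(rng, noise, parts, params.sentence_length)
            doc_id = f"D{i:03d}C{j}"
            source = rng.choice(["abstract", "fulltext"])
            title = " ".join(rng.choice(noise) for _ in range(3)).capitalize()
            doc = Document(doc_id, source, title, body)
            documents.append(doc)
            sent_index = _planted_sent_index(doc, body)
            gold.append(GoldLabel(qid, doc_id, sent_index, "context"))

    all_names = list(entity_surfaces)
    for k in range(params.n_distractor_docs):
        parts = []
        if all_names and rng.random() < 0.8:
            parts = [rng.choice(entity_surfaces[rng.choice(all_names)])]
        body = _sentence(rng, noise, parts, params.sentence_length)
        title = " ".join(rng.choice(noise) for _ in range(3)).capitalize()
        documents.append(
            Document(f"DX{k:04d}", rng.choice(["abstract", "fulltext"]), title, body)
        )

    return SyntheticCorpus(statements, documents, lexicon, gold)


def _planted_sent_index(doc: Document, body: str) -> int:
    for sent in doc_sentences(doc):
        if sent.text == body:
            return sent.sent_index
    raise AssertionError("planted sentence lost by the splitter")


# ---------------------------------------------------------------------------
# Classifier training data

def generate_relation_dataset(params: GeneratorParams) -> list[LabeledSentence]:
    """Balanced increase/decrease sentences with recorded entity spans.

    Each sentence embeds a contiguous subject-trigger-object core
    (``GENRA induces GENRB``, occasionally with one intervening noise
    word), the word order of causal assertions in prose, surrounded by
    noise tokens.  Class vocabularies are the built-in polarity trigger
    lists (disjoint between classes); with probability
    ``trigger_overlap`` the trigger is drawn from the pooled vocabulary
    instead, so overlap 1.0 leaves no class signal at all.
    """
    rng = random.Random(params.seed + 1)
    noise = _noise_vocabulary(rng)
    inc = list(_DEFAULT_TRIGGERS["increase"][: params.trigger_vocab_size])
    dec = list(_DEFAULT_TRIGGERS["decrease"][: params.trigger_vocab_size])
    pooled = inc + dec
    gene_pool = [f"GENR{_alpha_id(k)}" for k in range(20)]

    out: list[LabeledSentence] = []
    n = params.n_relation_sentences
    for i in range(n):
        label = "increase" if i < (n + 1) // 2 else "decrease"
        own = inc if label == "increase" else dec
        trigger = rng.choice(pooled if rng.random() < params.trigger_overlap else own)
        e1, e2 = rng.sample(gene_pool, 2)
        core = [e1, trigger]
        if rng.random() < 0.3:
            core.append(rng.choice(noise))
        core.append(e2)
        text = _sentence(rng, noise, [" ".join(core)], params.sentence_length)
        spans = tuple(
            (text.index(e), text.index(e) + len(e)) for e in (e1, e2)
        )
        out.append(LabeledSentence(text, spans, label))
    return out


def write_corpus(corpus: SyntheticCorpus, outdir) -> None:
    """Write statements.bel, corpus.jsonl, lexicon.tsv and gold.tsv."""
    import json
    from pathlib import Path

    from .lexicons import dump_entity_lexicon
    from .model import serialize_statement

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "statements.bel", "w", encoding="utf-8") as fh:
        for qid, stmt in corpus.statements.items():
            fh.write(f"{serialize_statement(stmt)}  # {qid}\n")
    with open(outdir / "corpus.jsonl", "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(json.dumps({
                "id": doc.doc_id, "source": doc.source,
                "title": doc.title, "text": doc.body,
            }) + "\n")
    dump_entity_lexicon(corpus.entity_lexicon, outdir / "lexicon.tsv")
    with open(outdir / "gold.tsv", "w", encoding="utf-8") as fh:
        for g in corpus.gold:
            fh.write(f"{g.query_id}\t{g.doc_id}\t{g.sent_index}\t{g.relevance}\n")
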