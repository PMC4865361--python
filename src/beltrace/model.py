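"""Data model, parser and serializer for BEL statements.

Biological Expression Language (BEL) statements are semantic triples
``subject relation object`` where subject and object are functional terms
over namespaced entities (e.g. ``p(HGNC:HSF1, pmod(P))``) and the relation
is one of four causal tokens.  The grammar implemented here is deliberately
whitespace-tolerant: curated statements in the wild print both
``HGNC: RPS6KA3`` and ``HGNC:RPS6KA3``, and spaces may appear around any
parenthesis or comma.  Serialization is canonical (no internal spaces, a
single space around the relation), so ``parse -> serialize`` normalizes a
statement and ``parse(serialize(x))`` is structurally identical to ``x``.

The function vocabulary is open: any token followed by ``(`` parses as a
function.  The five classical BEL function categories (abundances,
modifications, activities, processes, transformations) are labels on a
lexicon, not grammar restrictions, so statements using function tokens
unseen at development time still parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "EntityRef",
    "ModificationSpec",
    "BELTerm",
    "BELStatement",
    "BELParseError",
    "RELATIONS",
    "parse_statement",
    "serialize_statement",
    "collect_entities",
    "collect_functions",
    "relation_polarity",
    "iter_statements",
]

#: The four causal relation tokens.
RELATIONS = ("increases", "decreases", "directly increases", "directly decreases")

#: Function tokens whose argument list is a modification specification
#: (type, residue, position) rather than nested terms.
MOD_FUNCTIONS = frozenset({"pmod"})

#: Namespace spelling aliases, normalized at construction time.
_NAMESPACE_ALIASES = {"MESHD": "MESH"}


class BELParseError(ValueError):
    """Raised on malformed BEL input; carries the offending span."""

    def __init__(self, message: str, text: str = "", pos: int = 0):
        span = text[max(0, pos - 10): pos + 10]
        super().__init__(f"{message} at position {pos}: ...{span!r}...")
        self.pos = pos
        self.text = text


@dataclass(frozen=True)
class EntityRef:
    """A namespaced biological entity, e.g. ``HGNC:HSF1``.

    The namespace token is uppercase-normalized (``MESHD`` is aliased to
    ``MESH``); the name keeps its original casing.
    """

    namespace: str
    name: str

    def __post_init__(self):
        ns = self.namespace.strip().upper()
        ns = _NAMESPACE_ALIASES.get(ns, ns)
        object.__setattr__(self, "namespace", ns)
        object.__setattr__(self, "name", self.name.strip())
        if not self.name:
            raise ValueError("entity name must be non-empty")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.name}"


@dataclass(frozen=True)
class ModificationSpec:
    """Arguments of a protein-modification function, e.g. ``pmod(P,S,133)``.

    Stores exactly the 1-3 arguments given, in order: modification type,
    optionally the modified residue, optionally the sequence position.
    """

    mod_type: str
    residue: str | None = None
    position: int | None = None

    def arguments(self) -> list[str]:
        out = [self.mod_type]
        if self.residue is not None:
            out.append(self.residue)
        if self.position is not None:
            out.append(str(self.position))
        return out

    def __str__(self) -> str:
        return f"pmod({','.join(self.arguments())})"


TermArg = Union[EntityRef, "BELTerm", ModificationSpec]


@dataclass(frozen=True)
class BELTerm:
    """A BEL function applied to arguments.

    Arguments are entities, nested terms, or a trailing modification spec
    attached to an entity-headed term (``p(HGNC:HSF1, pmod(P))``).
    """

    function: str
    arguments: tuple[TermArg, ...]

    def __post_init__(self):
        if not self.arguments:
            raise ValueError(f"term {self.function}() has no arguments")
        for i, a in enumerate(self.arguments):
            if isinstance(a, ModificationSpec) and (
                i == 0 or not isinstance(self.arguments[0], EntityRef)
            ):
                raise ValueError(
                    "modification spec must trail an entity-headed term"
                )

    def __str__(self) -> str:
        return f"{self.function}({','.join(str(a) for a in self.arguments)})"


@dataclass(frozen=True)
class BELStatement:
    """``subject relation object``; the object may be a nested statement."""

    subject: BELTerm
    relation: str
    object: Union[BELTerm, "BELStatement"]

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation token {self.relation!r}")

    def __str__(self) -> str:
        obj = str(self.object)
        if isinstance(self.object, BELStatement):
            obj = f"({obj})"
        return f"{self.subject} {self.relation} {obj}"


# ---------------------------------------------------------------------------
# Parsing

_TOKEN_RE = re.compile(r"\s*([(),:]|[^\s(),:]+)")


class _TokenStream:
    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                break
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        if self.i < len(self.tokens):
            return self.tokens[self.i][1]
        return len(self.text)

    def next(self, expect: str | None = None, desc: str | None = None) -> str:
        if self.i >= len(self.tokens):
            raise BELParseError(
                f"unexpected end of statement (expected {desc or expect or 'more input'})",
                self.text,
                len(self.text),
            )
        tok, at = self.tokens[self.i]
        if expect is not None and tok != expect:
            raise BELParseError(
                f"expected {expect!r}, found {tok!r}", self.text, at
            )
        self.i += 1
        return tok


def _parse_modspec(ts: _TokenStream) -> ModificationSpec:
    ts.next("(")
    args: list[str] = []
    while True:
        tok = ts.next(desc="modification argument")
        if tok in "(),:":
            raise BELParseError("expected modification argument", ts.text, ts.pos())
        args.append(tok)
        nxt = ts.next()
        if nxt == ")":
            break
        if nxt != ",":
            raise BELParseError("expected ',' or ')'", ts.text, ts.pos())
    if len(args) > 3:
        raise BELParseError("pmod takes at most 3 arguments", ts.text, ts.pos())
    residue = args[1] if len(args) > 1 else None
    position: int | None = None
    if len(args) > 2:
        if not args[2].isdigit():
            raise BELParseError(
                f"sequence position must be numeric, got {args[2]!r}",
                ts.text,
                ts.pos(),
            )
        position = int(args[2])
    return ModificationSpec(args[0], residue, position)


def _parse_term(ts: _TokenStream) -> BELTerm:
    at = ts.pos()
    func = ts.next(desc="function token")
    if func in "(),:":
        raise BELParseError(f"expected function token, found {func!r}", ts.text, at)
    ts.next("(")
    args: list[TermArg] = []
    while True:
        at = ts.pos()
        head = ts.peek()
        if head is None:
            raise BELParseError("unbalanced parentheses", ts.text, at)
        if head in "(),:":
            raise BELParseError(f"expected argument, found {head!r}", ts.text, at)
        ts.next()
        nxt = ts.peek()
        if nxt == ":":
            ts.next(":")
            name = ts.next(desc="entity name")
            if name in "(),:":
                raise BELParseError("expected entity name after ':'", ts.text, at)
            args.append(EntityRef(head, name))
        elif nxt == "(":
            if head in MOD_FUNCTIONS:
                args.append(_parse_modspec(ts))
            else:
                ts.i -= 1  # rewind: head starts a nested term
                args.append(_parse_term(ts))
        else:
            raise BELParseError(
                f"bare token {head!r} is not a valid term argument", ts.text, at
            )
        sep = ts.next()
        if sep == ")":
            break
        if sep != ",":
            raise BELParseError(f"expected ',' or ')', found {sep!r}", ts.text, at)
    try:
        return BELTerm(func, tuple(args))
    except ValueError as e:
        raise BELParseError(str(e), ts.text, at) from e


def _parse_relation(ts: _TokenStream) -> str:
    at = ts.pos()
    tok = ts.next(desc="relation token")
    if tok == "directly":
        tok = f"directly {ts.next(desc='relation token')}"
    if tok not in RELATIONS:
        raise BELParseError(f"unknown relation token {tok!r}", ts.text, at)
    return tok


def _parse_statement(ts: _TokenStream) -> BELStatement:
    subject = _parse_term(ts)
    relation = _parse_relation(ts)
    if ts.peek() == "(":
        # a parenthesized object is a nested statement
        ts.next("(")
        obj: BELTerm | BELStatement = _parse_statement(ts)
        ts.next(")")
    else:
        obj = _parse_term(ts)
    return BELStatement(subject, relation, obj)


def parse_statement(text: str) -> BELStatement:
    """Parse one BEL statement from text.

    Tolerates arbitrary whitespace inside and around parentheses and after
    namespace colons.  Raises :class:`BELParseError` naming the offending
    span on unbalanced parentheses, unknown relation tokens, or empty
    argument lists.
    """
    if not text or not text.strip():
        raise BELParseError("empty statement", text or "", 0)
    ts = _TokenStream(text)
    stmt = _parse_statement(ts)
    if ts.peek() is not None:
        raise BELParseError(
            f"trailing input {ts.peek()!r} after statement", text, ts.pos()
        )
    return stmt


def serialize_statement(stmt: BELStatement) -> str:
    """Canonical single-line form, e.g. ``p(MGI:TNF) increases p(MGI:CREB1,pmod(P,S,133))``."""
    return str(stmt)


# ---------------------------------------------------------------------------
# Element collection

def _walk_terms(node: Union[BELTerm, BELStatement]) -> Iterator[BELTerm]:
    if isinstance(node, BELStatement):
        yield from _walk_terms(node.subject)
        yield from _walk_terms(node.object)
        return
    yield node
    for a in node.arguments:
        if isinstance(a, BELTerm):
            yield from _walk_terms(a)


def collect_entities(stmt: BELStatement) -> list[EntityRef]:
    """All entities in the statement, depth-first, first occurrence kept."""
    seen: dict[EntityRef, None] = {}
    for term in _walk_terms(stmt):
        for a in term.arguments:
            if isinstance(a, EntityRef):
                seen.setdefault(a)
    return list(seen)


def collect_functions(stmt: BELStatement) -> list[tuple[str, ModificationSpec | None]]:
    """Every function token in the tree, depth-first, with its modification
    arguments when it has them (``pmod`` entries carry their spec)."""
    out: list[tuple[str, ModificationSpec | None]] = []
    for term in _walk_terms(stmt):
        out.append((term.function, None))
        for a in term.arguments:
            if isinstance(a, ModificationSpec):
                out.append(("pmod", a))
    return out


def relation_polarity(relation: str) -> str:
    """Collapse the four relation tokens to ``increase`` / ``decrease``."""
    if relation in ("increases", "directly increases"):
        return "increase"
    if relation in ("decreases", "directly decreases"):
        return "decrease"
    raise ValueError(f"unknown relation token {relation!r}")


def iter_statements(lines) -> Iterator[BELStatement]:
    """Parse statements from an iterable of lines; '#' comments and blank
    lines are skipped."""
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            yield parse_statement(line)
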