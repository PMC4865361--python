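"""Translate a parsed BEL statement into a weighted boolean query.

Each distinct entity becomes a *required* OR-group (AND across groups)
holding the original name at weight 2 and each synonym at weight 1 — the
2:1 boost that favours the curated surface form over expansion terms.
Function tokens, modification arguments (type, residue, literal position)
and the relation polarity each become *optional* OR-groups of trigger
words at weight 1: they sharpen ranking but their absence never excludes
a citation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicons import (
    EntityLexicon,
    TriggerLexicon,
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

__all__ = ["QueryTerm", "ClauseGroup", "TranslatedQuery", "translate_statement"]

#: Default boost weights: names as written in the statement vs synonyms.
NAME_WEIGHT = 2.0
SYNONYM_WEIGHT = 1.0
TRIGGER_WEIGHT = 1.0


@dataclass(frozen=True)
class QueryTerm:
    """A word or phrase with its boost weight."""

    surface: str
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("query term weight must be positive")


@dataclass(frozen=True)
class ClauseGroup:
    """An OR-set of terms; required groups must match (boolean AND across
    groups), optional groups only contribute score."""

    terms: tuple[QueryTerm, ...]
    required: bool
    kind: str  # entity | function | function_arg | relation
    label: str = ""

    def __post_init__(self):
        if not self.terms:
            raise ValueError("clause group must have at least one term")


@dataclass(frozen=True)
class TranslatedQuery:
    groups: tuple[ClauseGroup, ...]
    statement: BELStatement

    def __post_init__(self):
        if not any(g.required for g in self.groups):
            raise ValueError("query must have at least one required group")
        if sum(1 for g in self.groups if g.kind == "relation") > 1:
            raise ValueError("query may have at most one relation group")

    def required_groups(self) -> list[ClauseGroup]:
        return [g for g in self.groups if g.required]


def translate_statement(
    stmt: BELStatement,
    entity_lex: EntityLexicon | None = None,
    trigger_lex: TriggerLexicon | None = None,
    *,
    include_function_groups: bool = True,
    name_weight: float = NAME_WEIGHT,
    synonym_weight: float = SYNONYM_WEIGHT,
) -> TranslatedQuery:
    """Build the weighted boolean query for a statement.

    Raises ``ValueError`` for a statement without entities (the query
    would be unbounded).  ``include_function_groups=False`` drops the
    optional function/argument groups from the retrieval query (they are
    always used again at ranking time regardless).
    """
    from .lexicons import default_trigger_lexicon

    entity_lex = entity_lex if entity_lex is not None else EntityLexicon()
    trigger_lex = (
        trigger_lex if trigger_lex is not None else default_trigger_lexicon()
    )

    entities = collect_entities(stmt)
    if not entities:
        raise ValueError("statement has no entities; refusing unbounded query")

    groups: list[ClauseGroup] = []
    for ent in entities:
        terms = [QueryTerm(ent.name, name_weight)]
        for syn in entity_synonyms(entity_lex, ent):
            terms.append(QueryTerm(syn, synonym_weight))
        groups.append(
            ClauseGroup(tuple(terms), required=True, kind="entity", label=str(ent))
        )

    if include_function_groups:
        seen_labels: set[str] = set()

        def add_optional(kind: str, label: str, surfaces: list[str]) -> None:
            if not surfaces or label in seen_labels:
                return
            seen_labels.add(label)
            groups.append(
                ClauseGroup(
                    tuple(QueryTerm(s, TRIGGER_WEIGHT) for s in surfaces),
                    required=False,
                    kind=kind,
                    label=label,
                )
            )

        for func, modspec in collect_functions(stmt):
            if modspec is None:
                add_optional("function", f"fn:{func}", function_triggers(trigger_lex, func))
            else:
                add_optional("function", "fn:pmod", function_triggers(trigger_lex, "pmod"))
                add_optional(
                    "function_arg",
                    f"mod:{modspec.mod_type}",
                    function_triggers(trigger_lex, modspec.mod_type),
                )
                if modspec.residue is not None:
                    add_optional(
                        "function_arg",
                        f"residue:{modspec.residue}",
                        function_triggers(trigger_lex, modspec.residue),
                    )
                if modspec.position is not None:
                    add_optional(
                        "function_arg",
                        f"pos:{modspec.position}",
                        [str(modspec.position)],
                    )

    polarity = relation_polarity(stmt.relation)
    rel_terms = relation_triggers(trigger_lex, polarity)
    if rel_terms:
        groups.append(
            ClauseGroup(
                tuple(QueryTerm(t, TRIGGER_WEIGHT) for t in rel_terms),
                required=False,
                kind="relation",
                label=polarity,
            )
        )

    return TranslatedQuery(tuple(groups), stmt)
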