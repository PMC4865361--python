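"""Synonym and trigger dictionaries.

Two dictionary families drive query expansion and element detection:

* an :class:`EntityLexicon` maps a namespaced entity to its synonym
  surface strings (gene full names, aliases, ...), loaded from a
  three-column TSV because the authoritative resources (HGNC, MGI,
  Entrez, GO) are too large to bundle and are licensed separately;
* a :class:`TriggerLexicon` maps polarity tokens, function tokens,
  modification-type codes and residue codes to the prose words that
  signal them ("increase" -> induce/activate, "P" -> phosphorylation,
  "S" -> serine, ...).

The shipped trigger defaults are a small expert-seeded vocabulary; a
user-supplied TSV replaces them entirely.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .model import EntityRef

__all__ = [
    "EntityLexicon",
    "TriggerLexicon",
    "load_entity_lexicon",
    "dump_entity_lexicon",
    "load_trigger_lexicon",
    "default_trigger_lexicon",
    "entity_synonyms",
    "relation_triggers",
    "function_triggers",
]

log = logging.getLogger(__name__)


@dataclass
class EntityLexicon:
    """Mapping from (namespace, name) to an ordered synonym list.

    Lookups are case-insensitive on namespace and exact-then-case-
    insensitive on name.  The name itself is never stored as a synonym.
    """

    _entries: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def add(self, namespace: str, name: str, synonym: str) -> None:
        synonym = synonym.strip()
        if not synonym:
            log.warning("skipping blank synonym for %s:%s", namespace, name)
            return
        key = (namespace.strip().upper(), name.strip())
        syns = self._entries.setdefault(key, [])
        if synonym != key[1] and synonym not in syns:
            syns.append(synonym)

    def synonyms(self, entity: EntityRef) -> list[str]:
        key = (entity.namespace, entity.name)
        if key in self._entries:
            return list(self._entries[key])
        low = entity.name.lower()
        for (ns, name), syns in self._entries.items():
            if ns == entity.namespace and name.lower() == low:
                return list(syns)
        return []

    def rows(self) -> list[tuple[str, str, str]]:
        return [
            (ns, name, syn)
            for (ns, name), syns in self._entries.items()
            for syn in syns
        ]

    def __len__(self) -> int:
        return len(self._entries)


def load_entity_lexicon(path) -> EntityLexicon:
    """Read an entity lexicon from a ``namespace<TAB>name<TAB>synonym`` TSV.

    One synonym per row; duplicate rows collapse; blank synonyms are
    skipped with a warning.  Rows with fewer than three columns raise a
    format error.
    """
    lex = EntityLexicon()
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(namespace, name, synonym), got {len(row)}"
                )
            lex.add(row[0], row[1], row[2])
    return lex


def dump_entity_lexicon(lex: EntityLexicon, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        for row in lex.rows():
            w.writerow(row)


# ---------------------------------------------------------------------------
# Triggers

#: Expert-seeded default trigger vocabulary.  Keys are polarity tokens,
#: function tokens (lowercase), modification-type and residue codes
#: (uppercase).  All triggers are lowercase surface strings.
_DEFAULT_TRIGGERS: dict[str, tuple[str, ...]] = {
    # relation polarities
    "increase": (
        "increase", "increases", "increased", "induce", "induces", "induced",
        "activate", "activates", "activated", "activation", "enhance",
        "enhances", "enhanced", "upregulate", "upregulates", "upregulated",
        "stimulate", "stimulates", "promotes",
    ),
    "decrease": (
        "decrease", "decreases", "decreased", "repress", "represses",
        "repressed", "inhibit", "inhibits", "inhibited", "inhibition",
        "reduce", "reduces", "reduced", "suppress", "suppresses",
        "suppressed", "downregulate", "downregulates", "downregulated",
    ),
    # functions
    "p": ("protein",),
    "r": ("mrna", "transcript"),
    "g": ("gene",),
    "a": ("abundance", "levels"),
    "kin": ("kinase", "kinase activity"),
    "phos": ("phosphatase",),
    "tscript": ("transcription", "transcriptional"),
    "bp": ("process", "pathway"),
    "pmod": ("modification", "modified"),
    # modification-type codes
    "P": ("phosphorylation", "phosphorylated", "phosphorylates", "phosphorylate"),
    "A": ("acetylation", "acetylated"),
    "U": ("ubiquitination", "ubiquitinated"),
    "M": ("methylation", "methylated"),
    # residue codes
    "S": ("serine", "ser"),
    "T": ("threonine", "thr"),
    "Y": ("tyrosine", "tyr"),
    "K": ("lysine", "lys"),
}


@dataclass
class TriggerLexicon:
    """Mapping from a key (polarity, function, mod-type or residue code)
    to its lowercase trigger surface strings."""

    _entries: dict[str, list[str]] = field(default_factory=dict)

    def add(self, key: str, trigger: str) -> None:
        trigger = trigger.strip().lower()
        if not trigger:
            return
        triggers = self._entries.setdefault(key.strip(), [])
        if trigger not in triggers:
            triggers.append(trigger)

    def triggers(self, key: str) -> list[str]:
        return list(self._entries.get(key, []))


def default_trigger_lexicon() -> TriggerLexicon:
    lex = TriggerLexicon()
    for key, triggers in _DEFAULT_TRIGGERS.items():
        for t in triggers:
            lex.add(key, t)
    return lex


def load_trigger_lexicon(path) -> TriggerLexicon:
    """Read a ``key<TAB>trigger`` TSV; the result replaces the defaults."""
    lex = TriggerLexicon()
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns "
                    f"(key, trigger), got {len(row)}"
                )
            lex.add(row[0], row[1])
    return lex


def entity_synonyms(lex: EntityLexicon, entity: EntityRef) -> list[str]:
    """Synonyms for an entity; ``[]`` when unknown, never the name itself."""
    return lex.synonyms(entity)


def relation_triggers(lex: TriggerLexicon, polarity: str) -> list[str]:
    """Trigger words for a relation polarity (``increase``/``decrease``)."""
    if polarity not in ("increase", "decrease"):
        raise ValueError(f"unknown polarity {polarity!r}")
    return lex.triggers(polarity)


def function_triggers(lex: TriggerLexicon, key: str) -> list[str]:
    """Trigger words for a function token, mod-type code or residue code;
    unknown keys yield ``[]``."""
    return lex.triggers(key)
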