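"""Knowledge bases as concepts, typed triples and information content.

A knowledge base (ontology) is loaded into a :class:`KnowledgeSource`:
a set of concepts (id, primary label, synonyms), a collection of
``(head, relation, tail)`` triples whose head and tail are concept surface
labels, and an intrinsic information-content (IC) score per concept.

IC is the descendant-count form

    IC(c) = -log( (descendants(c) + 1) / N )

computed over the transitive closure of ``is_a`` only, where ``N`` is the
total number of concepts.  Leaves attain the maximum ``-log(1/N)``; a root
from which every concept descends scores 0.  IC ranks competing triples when
more knowledge is available for an entity than the configured cap allows.
"""

from __future__ import annotations

import logging
import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")
_PUNCT = string.punctuation


class OntologyError(ValueError):
    """Structural problem in a knowledge source (e.g. an ``is_a`` cycle)."""


def normalize_surface(surface: str) -> str:
    """Normalize a surface form: lowercase, collapse internal whitespace,
    strip surrounding punctuation.  No stemming — chemistry nomenclature
    ("aralkylamino compound") must match exactly."""
    s = _WS_RE.sub(" ", surface.strip().lower())
    return s.strip(_PUNCT + " ")


@dataclass(frozen=True)
class Triple:
    """One knowledge-base association ``head --relation--> tail``.

    ``head`` and ``tail`` are concept surface labels (possibly multi-word);
    by convention the tail is the more general concept, so an injected branch
    reads child -> is_a -> parent.
    """

    head: str
    relation: str
    tail: str

    def __post_init__(self) -> None:
        if not (self.head and self.relation and self.tail):
            raise ValueError("triple fields must be non-empty")


@dataclass(frozen=True)
class Concept:
    id: str
    label: str
    synonyms: tuple[str, ...] = ()


@dataclass
class KnowledgeSource:
    """An ontology: concepts, triples and per-concept IC scores."""

    name: str
    concepts: dict[str, Concept]
    triples: list[Triple]
    relations: frozenset[str]
    ic: dict[str, float] = field(default_factory=dict)
    _label_to_ids: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._label_to_ids:
            index: dict[str, list[str]] = {}
            for cid, c in self.concepts.items():
                for form in (c.label, *c.synonyms):
                    index.setdefault(normalize_surface(form), []).append(cid)
            self._label_to_ids = {k: tuple(v) for k, v in index.items()}
        if not self.ic:
            self.ic = _compute_all_ic(self)

    def ids_for_label(self, surface: str) -> tuple[str, ...]:
        return self._label_to_ids.get(normalize_surface(surface), ())

    def concept_ic(self, concept_id: str) -> float:
        if concept_id not in self.ic:
            raise KeyError(f"unknown concept: {concept_id}")
        return self.ic[concept_id]

    def label_ic(self, surface: str) -> float:
        """IC of a surface label; label collisions resolve to the max IC."""
        ids = self.ids_for_label(surface)
        if not ids:
            return 0.0
        return max(self.ic[i] for i in ids)

    def tail_ic(self, triple: Triple) -> float:
        return self.label_ic(triple.tail)


def _is_a_graph(source: KnowledgeSource) -> nx.DiGraph:
    """Directed graph with an edge child -> parent for every is_a triple."""
    g = nx.DiGraph()
    g.add_nodes_from(source.concepts)
    for t in source.triples:
        if t.relation != "is_a":
            continue
        heads = source.ids_for_label(t.head)
        tails = source.ids_for_label(t.tail)
        for h in heads:
            for p in tails:
                if h != p:
                    g.add_edge(h, p)
    return g


def _compute_all_ic(source: KnowledgeSource) -> dict[str, float]:
    g = _is_a_graph(source)
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError(f"is_a cycle in knowledge source {source.name!r}")
    n = len(source.concepts)
    out: dict[str, float] = {}
    for cid in source.concepts:
        # nodes that reach cid along child->parent edges are its descendants
        desc = nx.ancestors(g, cid)
        # + 0.0 normalizes the -0.0 produced at a universal root
        out[cid] = (-math.log((len(desc) + 1) / n) + 0.0) if n else 0.0
    return out


def information_content(source: KnowledgeSource, concept_id: str) -> float:
    """Intrinsic IC of ``concept_id`` in ``source`` (descendant-count form)."""
    return source.concept_ic(concept_id)


def _parse_obo_synonym(raw: str) -> str | None:
    m = re.match(r'"((?:[^"\\]|\\.)*)"', raw)
    return m.group(1).replace('\\"', '"') if m else None


def load_knowledge_source(
    path: str | Path,
    format: str = "obo",
    name: str | None = None,
    index_synonyms: bool = True,
) -> KnowledgeSource:
    """Load a knowledge base from an OBO file or a 3-column TSV of triples.

    OBO: each ``is_a`` / ``relationship`` line becomes a
    ``(child label, relation, parent label)`` triple; obsolete terms are
    excluded; relationships to undefined terms are dropped with a warning.
    TSV: head ``\\t`` relation ``\\t`` tail per line, no header; concepts are
    the union of heads and tails, identified by their own label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name or path.stem
    if format == "obo":
        return _load_obo(path, name, index_synonyms)
    if format == "tsv-triples":
        return _load_tsv(path, name)
    raise ValueError(f"unknown knowledge-source format: {format!r}")


def _load_obo(path: Path, name: str, index_synonyms: bool) -> KnowledgeSource:
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    concepts: dict[str, Concept] = {}
    for node, data in graph.nodes(data=True):
        label = data.get("name")
        if label is None:
            logger.warning("term %s has no name; skipped", node)
            continue
        syns: tuple[str, ...] = ()
        if index_synonyms:
            syns = tuple(
                s for s in (_parse_obo_synonym(r) for r in data.get("synonym", ())) if s
            )
        concepts[node] = Concept(id=node, label=label, synonyms=syns)

    triples: list[Triple] = []
    relations: set[str] = set()
    for child, parent, rel in graph.edges(keys=True):
        if child not in concepts or parent not in concepts:
            logger.warning(
                "relationship %s -%s-> %s references an undefined term; dropped",
                child, rel, parent,
            )
            continue
        triples.append(Triple(concepts[child].label, rel, concepts[parent].label))
        relations.add(rel)
    return KnowledgeSource(
        name=name, concepts=concepts, triples=triples, relations=frozenset(relations)
    )


def _load_tsv(path: Path, name: str) -> KnowledgeSource:
    triples: list[Triple] = []
    relations: set[str] = set()
    labels: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            head, rel, tail = (p.strip() for p in parts)
            triples.append(Triple(head, rel, tail))
            relations.add(rel)
            labels.update((head, tail))
    concepts = {lab: Concept(id=lab, label=lab) for lab in sorted(labels)}
    return KnowledgeSource(
        name=name, concepts=concepts, triples=triples, relations=frozenset(relations)
    )


@dataclass
class LookupTable:
    """Normalized surface form -> triples whose head concept carries that form.

    Both the primary label and (optionally) every synonym of a concept map to
    the concept's triples.  When two concepts share a surface form their
    triple lists merge, ordered by descending tail IC.
    """

    source: str
    entries: dict[str, tuple[Triple, ...]]
    tail_ic: dict[Triple, float]
    normalization: str = "lowercase; collapse whitespace; strip outer punctuation"

    def get(self, surface: str) -> tuple[Triple, ...]:
        return self.entries.get(normalize_surface(surface), ())


def build_lookup(source: KnowledgeSource) -> LookupTable:
    """Build the surface-form lookup table for one knowledge source."""
    by_concept: dict[str, list[Triple]] = {cid: [] for cid in source.concepts}
    for t in source.triples:
        for cid in source.ids_for_label(t.head):
            by_concept[cid].append(t)

    tail_ic = {t: source.tail_ic(t) for t in source.triples}
    entries: dict[str, list[Triple]] = {}
    for cid, concept in source.concepts.items():
        for form in (concept.label, *concept.synonyms):
            key = normalize_surface(form)
            if not key:
                continue
            bucket = entries.setdefault(key, [])
            for t in by_concept[cid]:
                if t not in bucket:
                    bucket.append(t)
    ordered = {
        k: tuple(sorted(v, key=lambda t: (-tail_ic[t], t.relation, t.tail)))
        for k, v in entries.items()
    }
    return LookupTable(source=source.name, entries=ordered, tail_ic=tail_ic)


def query_surface(
    tables: Iterable[LookupTable], surface: str
) -> list[tuple[str, Triple]]:
    """Query every lookup table once; concatenate source-tagged results."""
    tables = list(tables)
    if not tables:
        raise ValueError("query_surface requires at least one lookup table")
    out: list[tuple[str, Triple]] = []
    for table in tables:
        out.extend((table.source, t) for t in table.get(surface))
    return out


def write_lookup_tsv(tables: Iterable[LookupTable], path: str | Path) -> None:
    """Serialize lookup tables as a sorted, diffable TSV."""
    rows = []
    for table in tables:
        for surface, triples in table.entries.items():
            for t in triples:
                rows.append(
                    (surface, table.source, t.head, t.relation, t.tail,
                     f"{table.tail_ic[t]:.6f}")
                )
    rows.sort()
    with Path(path).open("w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")
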