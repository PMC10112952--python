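"""Seeded toy ontologies and planted-signal relation-extraction corpora.

The generator emulates the statistical shape of a biomedical RE setup at
desk scale: a rooted ``is_a`` DAG with (partly multi-word) concept labels,
and sentences that mention two tagged candidate entities amid filler text.
The gold label is a noisy function of the entities' ontology ancestry —
"true" iff the two concepts share an ``is_a`` ancestor within a configurable
depth, flipped with probability ``label_noise`` — so injected ``is_a``
branches carry, by construction, the signal needed to recover the label.
A ``cue_strength``-controlled fraction of sentences also carries a weakly
label-correlated filler token, giving a knowledge-free model partial but
never full signal.

Everything is driven by one integer seed; the same spec reproduces
byte-identical OBO and corpus files.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .ontology import Concept, KnowledgeSource, Triple, load_knowledge_source
from .pipeline import RECorpus

_SYLLABLES = [
    "zor", "mel", "tan", "vex", "qui", "lor", "pha", "drin", "cos", "ald",
    "ben", "tri", "oxa", "nul", "gam", "sere", "vit", "kal", "myr", "plex",
]
_FILLERS = [
    "the", "a", "of", "with", "in", "was", "observed", "after", "treatment",
    "patients", "study", "reported", "increased", "decreased", "showed",
    "combination", "administration", "response", "levels", "during",
    "analysis", "clinical", "significant", "effects", "dose", "therapy",
    "measured", "compared", "group", "baseline",
]
_CUE_TRUE = ["synergistic", "coadministered", "interaction", "potentiated"]
_CUE_FALSE = ["unrelated", "independently", "separately", "background"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic ontology + corpus pair."""

    n_concepts: int = 40
    branching: int = 3               # is_a fan-out of the backbone tree
    #: "preferential" grows the tree by preferential attachment, giving the
    #: skewed family-size distribution real ontologies show (a few large
    #: families, many small ones); "balanced" uses the regular b-ary backbone
    attachment: str = "preferential"
    multiword_fraction: float = 0.15  # fraction of 2-3-word concept labels
    extra_parent_prob: float = 0.15  # chance of a second is_a parent (DAG)
    synonyms_per_concept: int = 12   # extra surface forms per concept
    n_sentences: int = 2000
    label_set: tuple[str, ...] = ("false", "true")
    ancestor_depth: int = 2          # shared-ancestor depth defining "true"
    #: materialize transitive is_a edges up to ancestor_depth, the way
    #: GO/ChEBI-style resources distribute inferred closures ("all types of
    #: relations are transitive"); every ancestor that can decide the label
    #: is then itself an injectable triple
    transitive_closure: bool = True
    cue_strength: float = 0.15       # P(label-correlated filler cue), "beta"
    label_noise: float = 0.1         # P(label flip), "epsilon"
    extra_entity_fraction: float = 0.3  # sentences with untagged KB concepts
    filler_range: tuple[int, int] = (2, 3)
    #: "stratified" oversamples the informative pair categories (shared
    #: parent / shared deeper ancestor / unrelated) so the planted ancestry
    #: signal is well represented; "uniform" samples concept pairs uniformly.
    pair_sampling: str = "stratified"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 1 or self.n_sentences < 1 or self.branching < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.cue_strength <= 1.0:
            raise ValueError("cue_strength must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")


def _make_label(spec: FixtureSpec, rng: np.random.Generator, seen: set[str]) -> str:
    while True:
        n_words = 1
        if rng.random() < spec.multiword_fraction:
            n_words = int(rng.integers(2, 4))
        label = " ".join(
            "".join(rng.choice(_SYLLABLES, size=int(rng.integers(2, 4))))
            for _ in range(n_words)
        )
        if label not in seen:
            seen.add(label)
            return label


def _concept_labels(
    spec: FixtureSpec,
    rng: np.random.Generator,
    forbidden: set[str] | None = None,
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Primary labels plus synonym surface forms per concept.

    Synonyms emulate the naming variety of biomedical text: a concept is
    mentioned in sentences under any of its surface forms, but only the
    ontology links those forms back to one node and its ancestry.
    ``forbidden`` labels are never reused (disjoint multi-source fixtures).
    """
    seen: set[str] = set(forbidden or ())
    labels = [_make_label(spec, rng, seen) for _ in range(spec.n_concepts)]
    synonyms = [
        tuple(_make_label(spec, rng, seen) for _ in range(spec.synonyms_per_concept))
        for _ in range(spec.n_concepts)
    ]
    return labels, synonyms


def generate_ontology(
    spec: FixtureSpec,
    name: str = "toy",
    forbidden_labels: set[str] | None = None,
) -> tuple[KnowledgeSource, str]:
    """Build a rooted is_a DAG and its OBO serialization.

    The backbone is a ``branching``-ary tree (node i's parent is node
    ``(i-1)//branching``); a fraction of non-root nodes gain a second,
    earlier parent so the graph is a genuine DAG, not a tree.
    """
    rng = np.random.default_rng(spec.seed)
    labels, synonyms = _concept_labels(spec, rng, forbidden_labels)
    ids = [f"TOY:{i:04d}" for i in range(spec.n_concepts)]
    concepts = {
        cid: Concept(id=cid, label=lab, synonyms=syns)
        for cid, lab, syns in zip(ids, labels, synonyms)
    }
    parents: dict[int, list[int]] = {}
    children = np.zeros(spec.n_concepts)
    for i in range(1, spec.n_concepts):
        if spec.attachment == "preferential" and i >= 2:
            # rich-get-richer fan-out, capped so no hub swallows the whole
            # ontology and the shared-ancestor predicate stays non-constant
            cap = 2 * spec.branching
            weights = np.where(
                children[:i] < cap, 1.0 + spec.branching * children[:i], 0.0
            )
            if weights.sum() == 0:
                weights = np.ones(i)
            main = int(rng.choice(i, p=weights / weights.sum()))
        else:
            main = (i - 1) // spec.branching
        ps = [main]
        children[main] += 1
        if i >= 2 and rng.random() < spec.extra_parent_prob:
            extra = int(rng.integers(0, i))
            if extra not in ps:
                # a second parent from strictly earlier nodes keeps it acyclic
                ps.append(extra)
                children[extra] += 1
        parents[i] = ps
    edges: dict[int, list[int]] = {i: list(ps) for i, ps in parents.items()}
    if spec.transitive_closure:
        for i in sorted(parents):
            frontier = set(parents[i])
            seen = set(frontier)
            for _ in range(spec.ancestor_depth - 1):
                frontier = {
                    gp for p in frontier for gp in parents.get(p, [])
                } - seen
                seen |= frontier
            edges[i] = sorted(seen)
    triples = [
        Triple(labels[i], "is_a", labels[p])
        for i in sorted(edges)
        for p in edges[i]
    ]
    source = KnowledgeSource(
        name=name, concepts=concepts, triples=triples, relations=frozenset({"is_a"})
    )
    obo = _to_obo(ids, labels, synonyms, edges, name)
    return source, obo


def _to_obo(ids, labels, synonyms, parents, name) -> str:
    lines = [
        "format-version: 1.2",
        f"ontology: {name}",
        "",
    ]
    for i, (cid, lab) in enumerate(zip(ids, labels)):
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {lab}")
        for syn in synonyms[i]:
            lines.append(f'synonym: "{syn}" EXACT []')
        for p in parents.get(i, []):
            lines.append(f"is_a: {ids[p]} ! {labels[p]}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _ancestors_within(
    parents: dict[str, list[str]], concept: str, depth: int
) -> set[str]:
    """is_a ancestors reachable in <= depth steps, including the concept."""
    frontier = {concept}
    seen = {concept}
    for _ in range(depth):
        frontier = {p for c in frontier for p in parents.get(c, [])} - seen
        seen |= frontier
    return seen


def ancestry_predicate(source: KnowledgeSource, depth: int):
    """Oracle: do two concept labels share an is_a ancestor within ``depth``?

    Computable from the ontology alone; it is the ceiling reference for any
    classifier on the generated corpus.
    """
    parents: dict[str, list[str]] = {}
    for t in source.triples:
        if t.relation == "is_a":
            parents.setdefault(t.head, []).append(t.tail)
    cache: dict[str, set[str]] = {}

    def anc(label: str) -> set[str]:
        if label not in cache:
            cache[label] = _ancestors_within(parents, label, depth)
        return cache[label]

    def predicate(a: str, b: str) -> bool:
        return bool(anc(a) & anc(b))

    return predicate


def corpus_predicate(source: KnowledgeSource, spec: FixtureSpec):
    """The gold-label predicate for a fixture.

    When the source materializes the transitive closure, one is_a hop
    already spans ``ancestor_depth`` levels of the base hierarchy, so a
    single hop realizes the same shared-ancestor-within-depth semantics.
    """
    hops = 1 if spec.transitive_closure else spec.ancestor_depth
    return ancestry_predicate(source, hops)


def generate_corpus(source: KnowledgeSource, spec: FixtureSpec) -> RECorpus:
    """Sample tagged candidate-relation sentences with a planted signal."""
    rng = np.random.default_rng(spec.seed + 1)
    concepts = list(source.concepts.values())
    labels = [c.label for c in concepts]
    surfaces = [(c.label, *c.synonyms) for c in concepts]
    if len(labels) < 2:
        raise ValueError("need at least two concepts to form candidate pairs")
    predicate = corpus_predicate(source, spec)
    related, unrelated = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        (related if predicate(labels[i], labels[j]) else unrelated).append((i, j))
    if not related or not unrelated:
        raise ValueError(
            "infeasible fixture: the ancestry predicate is constant over all "
            "concept pairs; adjust n_concepts/branching/ancestor_depth"
        )

    lab_false, lab_true = spec.label_set
    examples: list[tuple[str, str]] = []
    for _ in range(spec.n_sentences):
        if spec.pair_sampling == "stratified":
            # near-balanced classes regardless of ontology shape
            pool = related if rng.random() < 0.45 else unrelated
            i, j = pool[int(rng.integers(0, len(pool)))]
        else:
            i, j = rng.choice(len(labels), size=2, replace=False)
        # the predicate lives on the concepts; the sentence mentions them by
        # one of their surface forms, so text alone under-determines ancestry
        ent_a = str(rng.choice(surfaces[i]))
        ent_b = str(rng.choice(surfaces[j]))
        gold = predicate(labels[i], labels[j])
        if rng.random() < spec.label_noise:
            gold = not gold
        label = lab_true if gold else lab_false

        n_fill = int(rng.integers(spec.filler_range[0], spec.filler_range[1] + 1))
        words = list(rng.choice(_FILLERS, size=n_fill))
        if rng.random() < spec.cue_strength:
            cue_pool = _CUE_TRUE if gold else _CUE_FALSE
            words[int(rng.integers(0, n_fill))] = str(rng.choice(cue_pool))
        extras: list[str] = []
        if rng.random() < spec.extra_entity_fraction:
            n_extra = int(rng.integers(1, 4))
            pool = [k for k in range(len(labels)) if k not in (i, j)]
            picks = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
            extras = [str(rng.choice(surfaces[k])) for k in picks]

        slots = words + [f"<e>{ent_a}</e>", f"<e>{ent_b}</e>"] + extras
        order = rng.permutation(len(slots))
        text = " ".join(slots[k] for k in order) + " ."
        examples.append((label, text))
    return RECorpus(examples=examples, label_set=tuple(spec.label_set))


def generate_fixture(
    spec: FixtureSpec, outdir: str | Path, second_source: bool = False
) -> dict[str, Path]:
    """Write toy.obo (optionally toy2.obo), corpus.tsv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    source, obo = generate_ontology(spec, name="toy")
    paths = {"obo": outdir / "toy.obo", "corpus": outdir / "corpus.tsv",
             "manifest": outdir / "manifest.json"}
    paths["obo"].write_text(obo, encoding="utf-8")
    if second_source:
        spec2 = FixtureSpec(**{**asdict(spec), "seed": spec.seed + 1000})
        used = {
            form
            for c in source.concepts.values()
            for form in (c.label, *c.synonyms)
        }
        _, obo2 = generate_ontology(spec2, name="toy2", forbidden_labels=used)
        paths["obo2"] = outdir / "toy2.obo"
        paths["obo2"].write_text(obo2, encoding="utf-8")
    corpus = generate_corpus(source, spec)
    with paths["corpus"].open("w", encoding="utf-8") as fh:
        for label, text in corpus.examples:
            fh.write(f"{label}\t{text}\n")
    manifest = asdict(spec)
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, default=list) + "\n", encoding="utf-8"
    )
    # the written OBO must round-trip through the loader
    load_knowledge_source(paths["obo"], format="obo")
    return paths
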