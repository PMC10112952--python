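import numpy as np
import pytest

from kret.knowledge import Branch, SentenceTree
from kret.ontology import Concept, KnowledgeSource, Triple, build_lookup

TINY_OBO = """\
format-version: 1.2
ontology: tiny

[Term]
id: T:0001
name: compound

[Term]
id: T:0002
name: aralkylamino compound
synonym: "aralkylamine" EXACT []
is_a: T:0001 ! compound

[Term]
id: T:0003
name: dopamine
is_a: T:0002 ! aralkylamino compound

[Term]
id: T:0004
name: obsolete thing
is_obsolete: true
"""


@pytest.fixture
def tiny_obo(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO, encoding="utf-8")
    return path


def make_source(triples, name="toy", synonyms=None, extra_concepts=()):
    """KnowledgeSource from (head, relation, tail) tuples; labels double as ids."""
    labels = set(extra_concepts)
    for h, _, t in triples:
        labels.update((h, t))
    synonyms = synonyms or {}
    concepts = {
        lab: Concept(id=lab, label=lab, synonyms=tuple(synonyms.get(lab, ())))
        for lab in sorted(labels)
    }
    return KnowledgeSource(
        name=name,
        concepts=concepts,
        triples=[Triple(*t) for t in triples],
        relations=frozenset(r for _, r, _ in triples) or frozenset({"is_a"}),
    )


def random_dag_source(rng, n=50, name="dag"):
    """Random rooted is_a DAG over n concepts (labels c0..c{n-1})."""
    triples = []
    for i in range(1, n):
        parents = {int(rng.integers(0, i))}
        if rng.random() < 0.3:
            parents.add(int(rng.integers(0, i)))
        for p in parents:
            triples.append((f"c{i}", "is_a", f"c{p}"))
    return make_source(triples, name=name)


def random_tree(rng, max_trunk=12, max_anchors=3, max_branches=3):
    """Random sentence tree with non-overlapping anchors for seeing tests."""
    n = int(rng.integers(2, max_trunk + 1))
    trunk = [f"w{i}" for i in range(n)]
    anchors = {}
    pos = 0
    for _ in range(int(rng.integers(0, max_anchors + 1))):
        if pos >= n:
            break
        start = int(rng.integers(pos, n))
        end = min(n, start + int(rng.integers(1, 3)))
        n_br = int(rng.integers(1, max_branches + 1))
        branches = tuple(
            Branch(
                relation_tokens=("is_a",),
                tail_tokens=tuple(f"t{b}_{k}" for k in range(int(rng.integers(1, 4)))),
                ic=float(rng.random()),
                source="toy",
            )
            for b in range(n_br)
        )
        anchors[(start, end)] = branches
        pos = end + 1
    return SentenceTree(trunk=trunk, branches=anchors, label="true")


@pytest.fixture
def lookup_tiny():
    src = make_source(
        [
            ("dopamine", "is_a", "aralkylamino compound"),
            ("aralkylamino compound", "is_a", "organic amino compound"),
            ("seizure", "is_a", "abnormal nervous system physiology"),
            ("amino", "is_a", "fragment"),
        ],
        name="chebi",
    )
    return build_lookup(src)
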