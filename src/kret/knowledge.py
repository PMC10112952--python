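"""Knowledge layer: expand an entity-tagged sentence into a sentence tree.

A sentence is a token sequence with two marked candidate-entity spans.  The
knowledge layer matches token spans against one or more knowledge-base lookup
tables and attaches the matching triples as depth-1 branches at the matched
(anchor) spans, producing a :class:`SentenceTree`:

    t0 t1 ... ti {(r_i0, t_i0), ..., (r_ik, t_ik)} ... tn

Two injection modes exist: *targeted* queries only the two candidate-entity
spans; *contextual* queries every contiguous multi-token span in the sentence
and resolves overlaps in favour of the longest match.  The number of branches
per anchor is capped, keeping the highest-information-content tails.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from typing import Sequence

from .ontology import LookupTable, Triple

Span = tuple[int, int]  # half-open token-index range

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_PUNCT_CHARS = set(string.punctuation)

ENTITY_OPEN = "<e>"
ENTITY_CLOSE = "</e>"
_TAG_RE = re.compile(r"</?e>")


def tokenize(text: str) -> list[str]:
    """Split into word tokens (underscores kept) and single punctuation marks."""
    return _TOKEN_RE.findall(text)


def is_punctuation(token: str) -> bool:
    return bool(token) and all(ch in _PUNCT_CHARS for ch in token)


@dataclass
class Sentence:
    """Tokenized candidate relation: tokens, two entity spans, gold label."""

    tokens: list[str]
    entity_spans: tuple[Span, Span]
    label: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence has no tokens")
        (a0, a1), (b0, b1) = self.entity_spans
        n = len(self.tokens)
        if not (0 <= a0 < a1 <= n and 0 <= b0 < b1 <= n):
            raise ValueError("entity span out of bounds")
        if max(a0, b0) < min(a1, b1):
            raise ValueError("entity spans overlap")


def parse_tagged_sentence(text: str, label: str) -> Sentence:
    """Parse raw text with two ``<e>...</e>`` pairs into a :class:`Sentence`.

    The tags delimit the candidate entities; they are removed from the token
    sequence and never participate in matching.
    """
    tokens: list[str] = []
    spans: list[Span] = []
    pos = 0
    open_at: int | None = None
    for m in _TAG_RE.finditer(text):
        tokens.extend(tokenize(text[pos : m.start()]))
        if m.group() == ENTITY_OPEN:
            if open_at is not None:
                raise ValueError("nested <e> tag")
            open_at = len(tokens)
        else:
            if open_at is None:
                raise ValueError("</e> without matching <e>")
            if len(tokens) == open_at:
                raise ValueError("empty entity span")
            spans.append((open_at, len(tokens)))
            open_at = None
        pos = m.end()
    tokens.extend(tokenize(text[pos:]))
    if open_at is not None:
        raise ValueError("unclosed <e> tag")
    if len(spans) != 2:
        raise ValueError(f"expected exactly 2 tagged entities, found {len(spans)}")
    return Sentence(tokens=tokens, entity_spans=(spans[0], spans[1]), label=label)


def enumerate_spans(tokens: Sequence[str]) -> list[Span]:
    """All contiguous spans of one or more non-punctuation tokens.

    Punctuation tokens act as span separators: no span crosses or contains
    one.  For n punctuation-free tokens the count is n(n+1)/2.  Spans are
    emitted in (start ascending, length descending) order.
    """
    if not tokens:
        raise ValueError("no tokens")
    n = len(tokens)
    spans: list[Span] = []
    for start in range(n):
        if is_punctuation(tokens[start]):
            continue
        end = start
        while end < n and not is_punctuation(tokens[end]):
            end += 1
        spans.extend((start, stop) for stop in range(end, start, -1))
    return spans


@dataclass
class SpanMatch:
    """A token span matched in one knowledge source, with its triples."""

    span: Span
    source: str
    triples: tuple[Triple, ...]

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError("empty span")
        if not self.triples:
            raise ValueError("SpanMatch with no triples")


def _span_text(tokens: Sequence[str], span: Span) -> str:
    return " ".join(tokens[span[0] : span[1]])


def _overlaps(a: Span, b: Span) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _proper_subspan(a: Span, b: Span) -> bool:
    return b[0] <= a[0] and a[1] <= b[1] and a != b


def match_spans(
    tokens: Sequence[str],
    tables: Sequence[LookupTable],
    mode: str,
    entity_spans: tuple[Span, Span] | None = None,
) -> list[SpanMatch]:
    """Match token spans against the lookup tables.

    targeted
        Only the two candidate-entity spans are queried, each as a whole
        span, even if multi-token.
    contextual
        Every enumerated span is queried.  Among matched spans, proper
        sub-spans of other matched spans are discarded (longest match wins),
        then overlaps are resolved greedily by length, leftmost start, and
        higher summed tail IC, leaving pairwise non-overlapping spans.
    """
    if mode == "targeted":
        if entity_spans is None:
            raise ValueError("targeted mode requires entity spans")
        candidate = list(entity_spans)
    elif mode == "contextual":
        candidate = enumerate_spans(tokens)
    else:
        raise ValueError(f"unknown injection mode: {mode!r}")

    per_span: dict[Span, list[SpanMatch]] = {}
    for span in candidate:
        if span in per_span:
            continue
        surface = _span_text(tokens, span)
        hits = [
            SpanMatch(span, table.source, triples)
            for table in tables
            if (triples := table.get(surface))
        ]
        if hits:
            per_span[span] = hits

    if mode == "targeted":
        return [m for span in candidate for m in per_span.get(span, [])]

    def span_ic(span: Span) -> float:
        total = 0.0
        for m in per_span[span]:
            table = _table_by_name(tables, m.source)
            total += sum(table.tail_ic[t] for t in m.triples)
        return total

    matched = list(per_span)
    maximal = [
        s for s in matched if not any(_proper_subspan(s, other) for other in matched)
    ]
    maximal.sort(key=lambda s: (-(s[1] - s[0]), s[0], -span_ic(s)))
    kept: list[Span] = []
    for s in maximal:
        if not any(_overlaps(s, k) for k in kept):
            kept.append(s)
    kept.sort()
    return [m for span in kept for m in per_span[span]]


def _table_by_name(tables: Sequence[LookupTable], name: str) -> LookupTable:
    for t in tables:
        if t.source == name:
            return t
    raise KeyError(name)


@dataclass(frozen=True)
class ScoredTriple:
    source: str
    triple: Triple
    ic: float


@dataclass
class AnchorSelection:
    """The capped, IC-ordered knowledge kept for one anchor span."""

    span: Span
    picks: tuple[ScoredTriple, ...]


def select_branches(
    matches: Sequence[SpanMatch],
    max_entities: int | None,
    tables: Sequence[LookupTable],
) -> list[AnchorSelection]:
    """Cap the knowledge per anchor, keeping the highest-IC tails.

    Triples are pooled across sources per anchor span, de-duplicated, sorted
    by tail IC descending (ties: source name, then tail label) and truncated
    to ``max_entities`` (None = unbounded; the configured range is 2-5).
    """
    if max_entities is not None and max_entities < 1:
        raise ValueError("max_entities must be >= 1")
    pooled: dict[Span, dict[Triple, ScoredTriple]] = {}
    for m in matches:
        table = _table_by_name(tables, m.source)
        bucket = pooled.setdefault(m.span, {})
        for t in m.triples:
            st = ScoredTriple(m.source, t, table.tail_ic[t])
            prev = bucket.get(t)
            # identical triples from different sources collapse; keep the
            # higher-IC scoring, then the lexicographically first source
            if prev is None or (st.ic, prev.source) > (prev.ic, st.source):
                bucket[t] = st
    out: list[AnchorSelection] = []
    for span in sorted(pooled):
        ranked = sorted(
            pooled[span].values(),
            key=lambda s: (-s.ic, s.source, s.triple.tail),
        )
        if max_entities is not None:
            ranked = ranked[:max_entities]
        out.append(AnchorSelection(span=span, picks=tuple(ranked)))
    return out


@dataclass(frozen=True)
class Branch:
    """One depth-1 branch: tokenized relation + tokenized tail concept label.

    Relation labels stay single tokens (underscores intact, e.g. ``is_a``);
    tail labels split on whitespace so each word gets its own tree position.
    """

    relation_tokens: tuple[str, ...]
    tail_tokens: tuple[str, ...]
    ic: float
    source: str

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.relation_tokens + self.tail_tokens


@dataclass
class SentenceTree:
    """Trunk tokens plus depth-1 branches anchored at non-overlapping spans."""

    trunk: list[str]
    branches: dict[Span, tuple[Branch, ...]]
    label: str = ""

    def __post_init__(self) -> None:
        anchors = sorted(self.branches)
        for a, b in zip(anchors, anchors[1:]):
            if _overlaps(a, b):
                raise ValueError("overlapping anchors")


def _to_branch(pick: ScoredTriple) -> Branch:
    return Branch(
        relation_tokens=(pick.triple.relation,),
        tail_tokens=tuple(pick.triple.tail.split()),
        ic=pick.ic,
        source=pick.source,
    )


def build_sentence_tree(
    sentence: Sentence,
    tables: Sequence[LookupTable],
    mode: str,
    max_entities: int | None = None,
) -> SentenceTree:
    """Enumerate, match, cap, and assemble the sentence tree."""
    if mode == "none" or not tables:
        return SentenceTree(trunk=list(sentence.tokens), branches={}, label=sentence.label)
    matches = match_spans(sentence.tokens, tables, mode, sentence.entity_spans)
    selections = select_branches(matches, max_entities, tables)
    branches = {
        sel.span: tuple(_to_branch(p) for p in sel.picks)
        for sel in selections
        if sel.picks
    }
    return SentenceTree(trunk=list(sentence.tokens), branches=branches, label=sentence.label)
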