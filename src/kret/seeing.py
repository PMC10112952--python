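"""Embedding and Seeing layers: flatten a sentence tree for the encoder.

The tree is flattened to a single token sequence (branches inserted right
after their anchor's last trunk token).  Each token gets

* a hard position — its index in the flattened order,
* a soft position — its tree position: trunk tokens keep their trunk index;
  branch tokens continue counting from their anchor, so soft positions repeat
  across trunk and branches,
* a segment tag (all ``A`` for single-sentence relation extraction),
* a row/column in the boolean visible matrix.

Visibility encodes tree structure: trunk tokens see each other; a branch
token sees only its own branch and its anchor's trunk tokens.  The matrix is
symmetric with a true diagonal and later becomes the additive attention mask
that stops injected knowledge from perturbing unrelated sentence positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .knowledge import SentenceTree, Span

PAD_TOKEN = "[PAD]"
CLS_TOKEN = "[CLS]"

# token provenance markers used to compute soft positions and visibility
_TRUNK = "trunk"
_BRANCH = "branch"
_CLS = "cls"
_PAD = "pad"


@dataclass(frozen=True)
class Origin:
    kind: str                      # trunk | branch | cls | pad
    trunk_index: int = -1          # for trunk tokens
    anchor: Span | None = None     # for branch tokens
    branch_index: int = -1
    offset: int = -1               # position within the branch
    ic: float = math.inf           # branch IC; trunk/cls are never dropped first


@dataclass
class FlattenedInput:
    """Model-ready sequence: tokens, positions, segments, visible matrix."""

    tokens: list[str]
    origins: list[Origin]
    soft_pos: list[int] | None = None
    segment: list[str] = field(default_factory=list)
    visible: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segment:
            self.segment = ["A"] * len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def hard_pos(self) -> list[int]:
        return list(range(len(self.tokens)))


def flatten_tree(tree: SentenceTree) -> FlattenedInput:
    """Interleave trunk and branch tokens into the flattened order.

    Each anchor's branches are inserted immediately after the anchor's last
    trunk token, branch by branch in their kept order, each branch emitting
    its relation tokens then its tail tokens.
    """
    tokens: list[str] = []
    origins: list[Origin] = []
    anchors = sorted(tree.branches)
    anchor_at_end = {a[1] - 1: a for a in anchors}
    for i, tok in enumerate(tree.trunk):
        tokens.append(tok)
        origins.append(Origin(kind=_TRUNK, trunk_index=i))
        anchor = anchor_at_end.get(i)
        if anchor is None:
            continue
        for b_idx, branch in enumerate(tree.branches[anchor]):
            for off, btok in enumerate(branch.tokens):
                tokens.append(btok)
                origins.append(
                    Origin(
                        kind=_BRANCH,
                        anchor=anchor,
                        branch_index=b_idx,
                        offset=off,
                        ic=branch.ic,
                    )
                )
    return FlattenedInput(tokens=tokens, origins=origins, label=tree.label)


def assign_soft_positions(tree: SentenceTree, flattened: FlattenedInput) -> FlattenedInput:
    """Fill tree-derived soft positions.

    Trunk token i gets soft position i.  A branch continues from its anchor:
    its first token sits at (last anchor trunk index + 1), incrementing along
    the branch; sibling branches restart at the same offset; trunk tokens
    after the anchor keep their trunk indices, so duplicates are expected.
    """
    soft: list[int] = []
    for origin in flattened.origins:
        if origin.kind == _TRUNK:
            soft.append(origin.trunk_index)
        elif origin.kind == _BRANCH:
            assert origin.anchor is not None
            soft.append(origin.anchor[1] + origin.offset)
        elif origin.kind == _CLS:
            soft.append(0)
        else:
            soft.append(0)
    flattened.soft_pos = soft
    return flattened


def _mutually_visible(a: Origin, b: Origin) -> bool:
    if a.kind == _PAD or b.kind == _PAD:
        return False
    if a.kind == _BRANCH and b.kind == _BRANCH:
        return a.anchor == b.anchor and a.branch_index == b.branch_index
    if a.kind == _BRANCH or b.kind == _BRANCH:
        br, other = (a, b) if a.kind == _BRANCH else (b, a)
        if other.kind == _TRUNK:
            assert br.anchor is not None
            return br.anchor[0] <= other.trunk_index < br.anchor[1]
        return False  # cls (and pad) never see branch tokens
    return True  # trunk/cls <-> trunk/cls


def visible_matrix(tree: SentenceTree, flattened: FlattenedInput) -> np.ndarray:
    """Boolean pairwise-visibility matrix over the flattened order."""
    n = len(flattened)
    vis = np.zeros((n, n), dtype=bool)
    for i, oi in enumerate(flattened.origins):
        vis[i, i] = True
        for j in range(i + 1, n):
            if _mutually_visible(oi, flattened.origins[j]):
                vis[i, j] = vis[j, i] = True
    flattened.visible = vis
    return vis


def add_classification_token(
    flattened: FlattenedInput, cls_sees_branches: bool = False
) -> FlattenedInput:
    """Prepend a CLS-style classification token at hard 0, soft 0.

    All trunk soft positions shift by one.  By default CLS is visible to
    every trunk token and invisible to branch tokens, so classification
    reads sentence content but not raw injected knowledge; set
    ``cls_sees_branches`` to expose the branches directly.
    """
    if flattened.soft_pos is None or flattened.visible is None:
        raise ValueError("assign soft positions and visibility first")
    tokens = [CLS_TOKEN] + flattened.tokens
    origins = [Origin(kind=_CLS)] + flattened.origins
    soft = [0] + [p + 1 for p in flattened.soft_pos]
    n = len(tokens)
    vis = np.zeros((n, n), dtype=bool)
    vis[1:, 1:] = flattened.visible
    vis[0, 0] = True
    for j, origin in enumerate(flattened.origins, start=1):
        see = origin.kind == _TRUNK or (
            cls_sees_branches and origin.kind == _BRANCH
        )
        vis[0, j] = vis[j, 0] = see
    return FlattenedInput(
        tokens=tokens, origins=origins, soft_pos=soft,
        segment=["A"] * n, visible=vis, label=flattened.label,
    )


def _take(flattened: FlattenedInput, idx: list[int]) -> FlattenedInput:
    assert flattened.soft_pos is not None and flattened.visible is not None
    sel = np.asarray(idx)
    return FlattenedInput(
        tokens=[flattened.tokens[i] for i in idx],
        origins=[flattened.origins[i] for i in idx],
        soft_pos=[flattened.soft_pos[i] for i in idx],
        segment=[flattened.segment[i] for i in idx],
        visible=flattened.visible[np.ix_(sel, sel)],
        label=flattened.label,
    )


def truncate_pad(flattened: FlattenedInput, max_len: int) -> FlattenedInput:
    """Fit the sequence to ``max_len`` tokens.

    Overlong sequences drop whole branches first, lowest tail IC first (ties:
    the later branch in flattened order), then truncate the trunk tail.
    Short sequences are padded; PAD tokens are invisible to and from every
    real token (diagonal stays true).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if flattened.soft_pos is None or flattened.visible is None:
        raise ValueError("assign soft positions and visibility first")

    out = flattened
    while len(out) > max_len:
        branches: dict[tuple[Span, int], tuple[float, list[int]]] = {}
        for i, o in enumerate(out.origins):
            if o.kind == _BRANCH:
                assert o.anchor is not None
                key = (o.anchor, o.branch_index)
                branches.setdefault(key, (o.ic, []))[1].append(i)
        if branches:
            # drop the lowest-IC branch; ties resolved toward the later one
            drop_key = min(branches, key=lambda k: (branches[k][0], [-i for i in branches[k][1]]))
            drop = set(branches[drop_key][1])
            out = _take(out, [i for i in range(len(out)) if i not in drop])
        else:
            last_real = max(
                i for i, o in enumerate(out.origins) if o.kind in (_TRUNK, _CLS)
            )
            out = _take(out, [i for i in range(len(out)) if i != last_real])

    n = len(out)
    if n < max_len:
        pad = max_len - n
        vis = np.zeros((max_len, max_len), dtype=bool)
        vis[:n, :n] = out.visible
        np.fill_diagonal(vis, True)
        out = FlattenedInput(
            tokens=out.tokens + [PAD_TOKEN] * pad,
            origins=out.origins + [Origin(kind=_PAD)] * pad,
            soft_pos=(out.soft_pos or []) + [0] * pad,
            segment=out.segment + ["A"] * pad,
            visible=vis,
            label=out.label,
        )
    return out


def encode_tree(
    tree: SentenceTree,
    max_len: int,
    add_cls: bool = True,
    cls_sees_branches: bool = False,
) -> FlattenedInput:
    """flatten -> soft positions -> visible matrix (-> CLS) -> truncate/pad."""
    flat = flatten_tree(tree)
    assign_soft_positions(tree, flat)
    visible_matrix(tree, flat)
    if add_cls:
        flat = add_classification_token(flat, cls_sees_branches)
    return truncate_pad(flat, max_len)


def trim_common_padding(encoded: list[FlattenedInput]) -> list[FlattenedInput]:
    """Drop trailing PAD columns shared by every sequence in a batch.

    Padding tokens are invisible both ways, so removing columns that are
    PAD in *all* sequences changes no model output; it only shrinks the
    quadratic attention cost.
    """
    if not encoded:
        return encoded
    longest = max(
        (max((i for i, o in enumerate(f.origins) if o.kind != _PAD), default=-1) + 1)
        for f in encoded
    )
    longest = max(longest, 1)
    if longest == len(encoded[0]):
        return encoded
    keep = list(range(longest))
    return [_take(f, keep) for f in encoded]


def strip_branches(flattened: FlattenedInput) -> tuple[list[str], list[int]]:
    """Drop branch/pad/cls positions; return trunk tokens and soft positions."""
    toks, soft = [], []
    for tok, origin, sp in zip(
        flattened.tokens, flattened.origins, flattened.soft_pos or []
    ):
        if origin.kind == _TRUNK:
            toks.append(tok)
            soft.append(sp)
    return toks, soft
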