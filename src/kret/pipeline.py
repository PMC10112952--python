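"""Relation-extraction pipeline: corpus I/O, splitting, training, evaluation.

Corpora are label-TSV files, one candidate relation per line::

    effect\tThe interaction of <e>venlafaxine</e> with <e>seizure</e> ...

with exactly two ``<e>...</e>``-tagged entities per sentence.  The pipeline
splits stratified 60/10/30, computes inverse-frequency class weights,
injects knowledge into every split alike (knowledge plays no role before
fine-tuning), trains the mask transformer with Adam on class-weighted
cross-entropy, selects the best epoch on validation weighted F, and reports
support-weighted precision/recall/F plus accuracy.  Run-level differences
are compared with a one-tailed Welch t-test.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .knowledge import build_sentence_tree, parse_tagged_sentence
from .model import (
    EncodedBatch,
    MaskTransformer,
    ModelConfig,
    Vocabulary,
    batch_inputs,
    forward_classify,
    weighted_loss,
)
from .ontology import LookupTable
from .seeing import encode_tree, trim_common_padding

logger = logging.getLogger(__name__)


@dataclass
class RECorpus:
    """Labeled candidate-relation sentences with inline entity tags."""

    examples: list[tuple[str, str]]          # (label, tagged text)
    label_set: tuple[str, ...]
    errors: list[tuple[int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.examples)

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.examples]


def _validate_line(label: str, text: str, label_set: tuple[str, ...] | None) -> str | None:
    opens, closes = text.count("<e>"), text.count("</e>")
    if opens != 2 or closes != 2:
        return f"expected 2 tagged entities, found {min(opens, closes)}"
    try:
        parse_tagged_sentence(text, label)
    except ValueError as exc:
        return str(exc)
    if label_set is not None and label not in label_set:
        return f"unknown label {label!r}"
    return None


def read_corpus(
    path: str | Path, label_set: Sequence[str] | None = None
) -> RECorpus:
    """Parse a label-TSV corpus; malformed lines go into ``corpus.errors``."""
    declared = tuple(label_set) if label_set is not None else None
    examples: list[tuple[str, str]] = []
    errors: list[tuple[int, str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.lower().startswith("label\t"):
                continue  # optional header
            if "\t" not in line:
                errors.append((lineno, line, "no tab separator"))
                continue
            label, text = line.split("\t", 1)
            reason = _validate_line(label, text, declared)
            if reason is not None:
                errors.append((lineno, line, reason))
                continue
            examples.append((label, text))
    if not examples:
        raise ValueError(f"{path}: no valid corpus lines")
    labels = declared if declared is not None else tuple(sorted({l for l, _ in examples}))
    return RECorpus(examples=examples, label_set=labels, errors=errors)


def write_corpus(corpus: RECorpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for label, text in corpus.examples:
            fh.write(f"{label}\t{text}\n")


def _subset(corpus: RECorpus, idx: Sequence[int]) -> RECorpus:
    return RECorpus(
        examples=[corpus.examples[i] for i in idx], label_set=corpus.label_set
    )


def split_corpus(
    corpus: RECorpus,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> tuple[RECorpus, RECorpus, RECorpus]:
    """Label-stratified, seeded train/validation/test partition.

    Per-label counts are allocated by largest remainder, so each split's
    label proportions stay within one example of the global proportions.
    Labels with fewer examples than splits are assigned round-robin with a
    warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for label in corpus.label_set:
        idx = [i for i, (lab, _) in enumerate(corpus.examples) if lab == label]
        rng.shuffle(idx)
        if 0 < len(idx) < len(fractions):
            logger.warning("label %r has only %d examples; round-robin split", label, len(idx))
            for j, i in enumerate(idx):
                parts[j % 3].append(i)
            continue
        raw = [f * len(idx) for f in fractions]
        counts = [int(r) for r in raw]
        rem = sorted(range(3), key=lambda j: raw[j] - counts[j], reverse=True)
        for j in rem[: len(idx) - sum(counts)]:
            counts[j] += 1
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start : start + c])
            start += c
    return tuple(_subset(corpus, sorted(p)) for p in parts)  # type: ignore[return-value]


def compute_class_weights(train: RECorpus) -> np.ndarray:
    """Inverse-frequency class weights w_c = N / (L * n_c).

    The support-weighted mean of the weights is identically 1, so the
    weighted loss stays on the scale of unweighted cross-entropy.
    """
    labels = train.labels()
    n = len(labels)
    L = len(train.label_set)
    weights = np.empty(L)
    for c, label in enumerate(train.label_set):
        n_c = labels.count(label)
        if n_c == 0:
            raise ValueError(f"label {label!r} absent from the training split")
        weights[c] = n / (L * n_c)
    return weights


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Per-label and support-weighted precision/recall/F, plus accuracy."""

    labels: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f_measure: dict[str, float]
    support: dict[str, int]
    weighted_precision: float
    weighted_recall: float
    weighted_f: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "per_label": {
                lab: {
                    "precision": self.precision[lab],
                    "recall": self.recall[lab],
                    "f_measure": self.f_measure[lab],
                    "support": self.support[lab],
                }
                for lab in self.labels
            },
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f": self.weighted_f,
            "accuracy": self.accuracy,
        }


def evaluate(
    predictions: Sequence[str], gold: Sequence[str], label_set: Sequence[str]
) -> EvalReport:
    """Confusion-matrix metrics with support-weighted averages."""
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold differ in length")
    if not gold:
        raise ValueError("nothing to evaluate")
    labels = tuple(label_set)
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, g in zip(predictions, gold):
        cm[index[g], index[p]] += 1

    precision, recall, f_measure, support = {}, {}, {}, {}
    for lab, i in index.items():
        tp = cm[i, i]
        pred_i = cm[:, i].sum()
        gold_i = cm[i, :].sum()
        prec = tp / pred_i if pred_i else 0.0
        rec = tp / gold_i if gold_i else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precision[lab], recall[lab], f_measure[lab] = prec, rec, f
        support[lab] = int(gold_i)
    total = cm.sum()
    wp = sum(precision[l] * support[l] for l in labels) / total
    wr = sum(recall[l] * support[l] for l in labels) / total
    wf = sum(f_measure[l] * support[l] for l in labels) / total
    acc = cm.trace() / total
    return EvalReport(labels, precision, recall, f_measure, support,
                      float(wp), float(wr), float(wf), float(acc))


def significance(runs_a: Sequence[float], runs_b: Sequence[float]) -> float:
    """One-tailed Welch t-test p-value for mean(b) > mean(a)."""
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("need at least two runs per side")
    a, b = np.asarray(runs_a, float), np.asarray(runs_b, float)
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.5
        return 0.0 if b.mean() > a.mean() else 1.0
    return float(stats.ttest_ind(b, a, equal_var=False, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# training

@dataclass
class InjectionConfig:
    mode: str = "contextual"           # targeted | contextual | none
    max_entities: int | None = 2       # knowledge entities per sentence entity
    cls_sees_branches: bool = False    # expose branches to the CLS row


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    warmup_fraction: float = 0.1
    schedule: str = "linear"           # linear decay after warmup | constant
    seed: int = 0


@dataclass
class TrainedModel:
    model: MaskTransformer
    vocab: Vocabulary
    label_set: tuple[str, ...]
    history: list[dict]
    injection: InjectionConfig


def _encode_split(
    corpus: RECorpus,
    tables: Sequence[LookupTable],
    injection: InjectionConfig,
    max_len: int,
):
    encoded = []
    for label, text in corpus.examples:
        sent = parse_tagged_sentence(text, label)
        tree = build_sentence_tree(sent, tables, injection.mode, injection.max_entities)
        encoded.append(
            encode_tree(tree, max_len, cls_sees_branches=injection.cls_sees_branches)
        )
    return trim_common_padding(encoded)


def _adam_step(params, grads, state, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for name, g in grads.items():
        m = state["m"][name] = beta1 * state["m"][name] + (1 - beta1) * g
        v = state["v"][name] = beta2 * state["v"][name] + (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[name] -= lr * mhat / (np.sqrt(vhat) + eps)


def predict(
    model: MaskTransformer,
    batch: EncodedBatch,
    label_set: Sequence[str],
    batch_size: int = 64,
) -> list[str]:
    out: list[str] = []
    n = batch.ids.shape[0]
    for s in range(0, n, batch_size):
        sl = slice(s, s + batch_size)
        logits = model.forward(
            batch.ids[sl], batch.soft[sl], batch.seg[sl], batch.visible[sl]
        )
        out.extend(label_set[i] for i in logits.argmax(1))
    return out


def train(
    splits: tuple[RECorpus, RECorpus, RECorpus],
    tables: Sequence[LookupTable],
    injection: InjectionConfig,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
) -> tuple[TrainedModel, EvalReport]:
    """Fine-tune the mask transformer and report test metrics.

    Knowledge injection runs identically on train/validation/test; the
    best-validation-weighted-F epoch's parameters are restored before the
    final test evaluation.  Deterministic under fixed seeds.
    """
    tc = train_config or TrainConfig()
    train_c, val_c, test_c = splits
    label_set = train_c.label_set
    label_ids = {lab: i for i, lab in enumerate(label_set)}

    enc = {
        name: _encode_split(split, tables, injection, model_config.max_len)
        for name, split in (("train", train_c), ("val", val_c), ("test", test_c))
    }
    vocab = Vocabulary(
        tok for split in enc.values() for f in split for tok in f.tokens
    )
    model_config.vocab_size = max(model_config.vocab_size, len(vocab))
    model_config.class_weights = compute_class_weights(train_c)
    model_config.n_labels = len(label_set)

    model = MaskTransformer(model_config)
    batches = {k: batch_inputs(v, vocab, label_ids) for k, v in enc.items()}

    rng = np.random.default_rng(tc.seed)
    state = {
        "t": 0,
        "m": {k: np.zeros_like(v) for k, v in model.params.items()},
        "v": {k: np.zeros_like(v) for k, v in model.params.items()},
    }
    n_train = len(train_c)
    steps_per_epoch = max(1, int(np.ceil(n_train / tc.batch_size)))
    total_steps = max(1, tc.epochs * steps_per_epoch)
    warmup = max(1, int(tc.warmup_fraction * total_steps))

    history: list[dict] = []
    best_f, best_params = -1.0, copy.deepcopy(model.params)
    tb = batches["train"]
    for epoch in range(tc.epochs):
        order = rng.permutation(n_train)
        losses = []
        for s in range(0, n_train, tc.batch_size):
            idx = order[s : s + tc.batch_size]
            logits = model.forward(
                tb.ids[idx], tb.soft[idx], tb.seg[idx], tb.visible[idx],
                train=True, rng=rng,
            )
            loss, dlogits = weighted_loss(
                logits, tb.labels[idx], model_config.class_weights
            )
            grads = model.backward(dlogits)
            step = state["t"] + 1
            if step < warmup:
                lr = tc.learning_rate * step / warmup
            elif tc.schedule == "constant":
                lr = tc.learning_rate
            else:
                lr = tc.learning_rate * max(
                    0.0, (total_steps - step) / max(1, total_steps - warmup)
                )
            _adam_step(model.params, grads, state, lr)
            losses.append(loss)
        val_pred = predict(model, batches["val"], label_set)
        val_report = evaluate(val_pred, val_c.labels(), label_set)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_weighted_f": val_report.weighted_f}
        )
        if val_report.weighted_f > best_f:
            best_f = val_report.weighted_f
            best_params = copy.deepcopy(model.params)
    if tc.epochs > 0:
        model.params = best_params

    test_pred = predict(model, batches["test"], label_set)
    report = evaluate(test_pred, test_c.labels(), label_set)
    trained = TrainedModel(model, vocab, label_set, history, injection)
    return trained, report
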