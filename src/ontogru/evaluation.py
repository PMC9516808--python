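"""Ontology-aware evaluation: modified F1, Jaccard semantic similarity,
per-sub-ontology breakdowns, error fractions and confidence diagnostics.

The modified F1 is a micro-averaged token-level F1 that omits positions
where the out-of-concept tag ('O', and likewise 'EOS') is predicted
correctly; the dominant non-annotation class would otherwise inflate the
score.  The semantic variant grants partial credit for near-miss concept
predictions through the Jaccard similarity of is_a ancestor sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ontogru.datatypes import (
    EOS_TAG,
    O_TAG,
    OntologyGraph,
    concept_of,
    is_go_tag,
)

log = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "ConfusionMatrix",
    "modified_f1",
    "jaccard_similarity",
    "semantic_f1",
    "confusion_by_namespace",
    "error_breakdown",
    "frequency_binned_f1",
    "confidence_table",
    "evaluate_tags",
    "DEFAULT_FREQUENCY_EDGES",
]

CONFUSION_CLASSES = ("GO_BP", "GO_MF", "GO_CC", "O", "EOS")
DEFAULT_FREQUENCY_EDGES = (1, 10, 20, 50, 100)

TagSeqs = Sequence[Sequence[str]]


def _check_aligned(gold: TagSeqs, pred: TagSeqs) -> None:
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} predicted sequences")
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(
                f"sequence {i}: {len(g)} gold vs {len(p)} predicted tags"
            )


def _positions(gold: TagSeqs, pred: TagSeqs):
    """All aligned (gold_tag, pred_tag) pairs except correctly predicted
    non-annotation positions (gold == pred in {O, EOS})."""
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            if g == p and g in (O_TAG, EOS_TAG):
                continue
            yield g, p


def modified_f1(gold: TagSeqs, pred: TagSeqs) -> tuple[float, float, float]:
    """Micro precision/recall/F1 over token tags, omitting correct O/EOS.

    A true positive is an exact tag match (B-/I- prefix included) on a GO
    tag; 0/0 ratios resolve to 0.
    """
    _check_aligned(gold, pred)
    tp = fp = fn = 0
    for g, p in _positions(gold, pred):
        if is_go_tag(p):
            if g == p:
                tp += 1
            else:
                fp += 1
        if is_go_tag(g) and g != p:
            fn += 1
    return _prf(tp, tp, tp + fp, tp + fn)


def _prf(num_p, num_r, den_p, den_r) -> tuple[float, float, float]:
    if den_p == 0:
        log.warning("no predicted concept tags; precision defined as 0")
    if den_r == 0:
        log.warning("no gold concept tags; recall defined as 0")
    precision = num_p / den_p if den_p else 0.0
    recall = num_r / den_r if den_r else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def jaccard_similarity(a: str, b: str, onto: OntologyGraph) -> float:
    """|Anc(a) & Anc(b)| / |Anc(a) | Anc(b)| with self-inclusive is_a
    ancestor sets; 0 (with a warning) when either concept is unknown."""
    if a not in onto or b not in onto:
        log.warning("concept %s or %s not in ontology; similarity 0", a, b)
        return 0.0
    anc_a, anc_b = onto.ancestors(a), onto.ancestors(b)
    return len(anc_a & anc_b) / len(anc_a | anc_b)


def semantic_f1(
    gold: TagSeqs, pred: TagSeqs, onto: OntologyGraph
) -> tuple[float, float, float]:
    """Like modified_f1 but positions where gold and prediction are both GO
    tags earn the Jaccard similarity of their concepts as fractional credit
    (prefixes are not compared); denominators are unchanged."""
    _check_aligned(gold, pred)
    credit = 0.0
    n_pred = n_gold = 0
    for g, p in _positions(gold, pred):
        g_go, p_go = is_go_tag(g), is_go_tag(p)
        if p_go:
            n_pred += 1
        if g_go:
            n_gold += 1
        if g_go and p_go:
            if concept_of(g) == concept_of(p):
                credit += 1.0
            else:
                credit += jaccard_similarity(concept_of(g), concept_of(p), onto)
    return _prf(credit, credit, n_pred, n_gold)


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class counts over {GO_BP, GO_MF, GO_CC, O, EOS};
    correctly predicted O/EOS positions are tallied separately as excluded."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            t: {p: 0 for p in CONFUSION_CLASSES} for t in CONFUSION_CLASSES
        }
    )
    excluded: int = 0

    @property
    def total(self) -> int:
        return sum(sum(row.values()) for row in self.counts.values())

    def to_rows(self) -> list[list]:
        header = ["true\\pred", *CONFUSION_CLASSES]
        rows = [header]
        for t in CONFUSION_CLASSES:
            rows.append([t, *(self.counts[t][p] for p in CONFUSION_CLASSES)])
        return rows


def _tag_class(tag: str, onto: OntologyGraph) -> str:
    if tag == O_TAG:
        return "O"
    if tag == EOS_TAG:
        return "EOS"
    code = onto.namespace_code(concept_of(tag))
    if code not in ("BP", "CC", "MF"):
        log.warning("concept %s has no GO namespace; bucketed as O", concept_of(tag))
        return "O"
    return f"GO_{code}"


def confusion_by_namespace(
    gold: TagSeqs, pred: TagSeqs, onto: OntologyGraph
) -> ConfusionMatrix:
    """Confusion matrix with concepts mapped to their sub-ontology."""
    _check_aligned(gold, pred)
    cm = ConfusionMatrix()
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            if g == p and g in (O_TAG, EOS_TAG):
                cm.excluded += 1
                continue
            cm.counts[_tag_class(g, onto)][_tag_class(p, onto)] += 1
    return cm


def error_breakdown(gold: TagSeqs, pred: TagSeqs) -> dict[str, float]:
    """Fractions of exact-correct, GO->non-annotation, non-annotation->GO
    and GO->different-GO outcomes over the non-excluded positions.

    When every position is an accurately predicted non-annotation the
    convention (1, 0, 0, 0) is returned with a warning.
    """
    _check_aligned(gold, pred)
    keys = ("correct", "go_to_o", "o_to_go", "go_to_wrong_go")
    counts = dict.fromkeys(keys, 0)
    total = 0
    for g, p in _positions(gold, pred):
        total += 1
        if g == p:
            counts["correct"] += 1
        elif is_go_tag(g) and not is_go_tag(p):
            counts["go_to_o"] += 1
        elif is_go_tag(g) and is_go_tag(p):
            counts["go_to_wrong_go"] += 1
        else:
            # gold O/EOS predicted as a concept (or as the other non-GO tag)
            counts["o_to_go"] += 1
    if total == 0:
        log.warning("no non-excluded positions; error breakdown degenerate")
        return {"correct": 1.0, "go_to_o": 0.0, "o_to_go": 0.0, "go_to_wrong_go": 0.0}
    return {k: v / total for k, v in counts.items()}


def per_concept_f1(gold: TagSeqs, pred: TagSeqs) -> dict[str, float]:
    """Micro F1 per concept id over the positions mentioning it."""
    _check_aligned(gold, pred)
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            if is_go_tag(g):
                c = concept_of(g)
                if g == p:
                    tp[c] = tp.get(c, 0) + 1
                else:
                    fn[c] = fn.get(c, 0) + 1
            if is_go_tag(p) and g != p:
                c = concept_of(p)
                fp[c] = fp.get(c, 0) + 1
    scores = {}
    for c in set(tp) | set(fp) | set(fn):
        t, f_p, f_n = tp.get(c, 0), fp.get(c, 0), fn.get(c, 0)
        denom = 2 * t + f_p + f_n
        scores[c] = 2 * t / denom if denom else 0.0
    return scores


def frequency_binned_f1(
    gold: TagSeqs,
    pred: TagSeqs,
    train_counts: Mapping[str, int],
    bin_edges: Sequence[int] = DEFAULT_FREQUENCY_EDGES,
) -> dict[str, list[float]]:
    """Per-concept F1 grouped by the concept's training-corpus frequency.

    Edges (e1, ..., ek) make bins [e1, e2), ..., [ek, inf) labelled
    "e1-e2", ..., "ek+"; concepts absent from the training counts go to
    "unseen".
    """
    edges = list(bin_edges)
    labels = [f"{a}-{b}" for a, b in zip(edges, edges[1:])] + [f"{edges[-1]}+"]
    bins: dict[str, list[float]] = {lab: [] for lab in labels}
    bins["unseen"] = []
    for concept, f1 in sorted(per_concept_f1(gold, pred).items()):
        count = train_counts.get(concept)
        if not count:
            bins["unseen"].append(f1)
            continue
        label = labels[-1]
        for a, b, lab in zip(edges, edges[1:], labels):
            if a <= count < b:
                label = lab
                break
        bins[label].append(f1)
    return bins


def train_tag_counts(sentences) -> dict[str, int]:
    """Occurrences per concept id in training data (one count per tagged
    token position, B- and I- alike)."""
    counts: dict[str, int] = {}
    for sent in sentences:
        for tag in sent.tags:
            if is_go_tag(tag):
                c = concept_of(tag)
                counts[c] = counts.get(c, 0) + 1
    return counts


def confidence_table(
    gold: TagSeqs,
    pred: TagSeqs,
    predictions,
    train_counts: Mapping[str, int],
    tag_vocab,
) -> list[dict]:
    """One row per non-excluded position where either side is a GO tag:
    entropy, top probability, training frequency of the gold concept, and
    correctness.  Raw material for confidence/frequency diagnostics."""
    rows = []
    for g_seq, p_seq, preds in zip(gold, pred, predictions):
        for g, p, tok_pred in zip(g_seq, p_seq, preds):
            if not (is_go_tag(g) or is_go_tag(p)):
                continue
            freq = train_counts.get(concept_of(g), 0) if is_go_tag(g) else 0
            rows.append(
                {
                    "entropy": tok_pred.entropy,
                    "top_probability": float(tok_pred.probabilities.max()),
                    "frequency": freq,
                    "correct": g == p,
                }
            )
    return rows


@dataclass
class EvalReport:
    """Full evaluation bundle for one prediction run."""

    modified_precision: float
    modified_recall: float
    modified_f1: float
    semantic_precision: float
    semantic_recall: float
    semantic_f1: float
    per_namespace_f1: dict[str, float]
    confusion: ConfusionMatrix
    error_breakdown: dict[str, float]
    frequency_bins: dict[str, list[float]]

    def to_dict(self) -> dict:
        return {
            "modified_precision": self.modified_precision,
            "modified_recall": self.modified_recall,
            "modified_f1": self.modified_f1,
            "semantic_precision": self.semantic_precision,
            "semantic_recall": self.semantic_recall,
            "semantic_f1": self.semantic_f1,
            "per_namespace_f1": self.per_namespace_f1,
            "confusion": {
                "counts": self.confusion.counts,
                "excluded": self.confusion.excluded,
            },
            "error_breakdown": self.error_breakdown,
            "frequency_bins": self.frequency_bins,
        }


def _namespace_f1(gold: TagSeqs, pred: TagSeqs, onto: OntologyGraph) -> dict[str, float]:
    out = {}
    for code in ("BP", "CC", "MF"):
        def keep(tag: str) -> str:
            if is_go_tag(tag) and onto.namespace_code(concept_of(tag)) != code:
                return O_TAG
            return tag

        g_sub = [[keep(t) for t in seq] for seq in gold]
        p_sub = [[keep(t) for t in seq] for seq in pred]
        out[code] = modified_f1(g_sub, p_sub)[2]
    return out


def evaluate_tags(
    gold: TagSeqs,
    pred: TagSeqs,
    onto: OntologyGraph,
    train_counts: Mapping[str, int] | None = None,
    bin_edges: Sequence[int] = DEFAULT_FREQUENCY_EDGES,
) -> EvalReport:
    """Compute the full report from aligned gold/predicted tag sequences."""
    train_counts = train_counts or {}
    mp, mr, mf = modified_f1(gold, pred)
    sp, sr, sf = semantic_f1(gold, pred, onto)
    return EvalReport(
        modified_precision=mp,
        modified_recall=mr,
        modified_f1=mf,
        semantic_precision=sp,
        semantic_recall=sr,
        semantic_f1=sf,
        per_namespace_f1=_namespace_f1(gold, pred, onto),
        confusion=confusion_by_namespace(gold, pred, onto),
        error_breakdown=error_breakdown(gold, pred),
        frequency_bins=frequency_binned_f1(gold, pred, train_counts, bin_edges),
    )
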