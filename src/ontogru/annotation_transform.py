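"""Sentence segmentation and conversion of character-span annotations into
per-token IOB training sentences.

A corpus sentence may carry four kinds of annotations:

* disjoint -- non-overlapping spans, tagged in place;
* overlapping -- a phrase annotated to one concept containing a sub-phrase
  annotated to another: the sentence is copied once per alternative, and each
  copy keeps only the tokens of its chosen alternative;
* multiply overlapping -- m overlap groups with n1..nm alternatives expand to
  the full Cartesian product of n1 x ... x nm copies;
* discontinuous -- a multi-span annotation: the unannotated tokens between
  its spans are deleted so the concept becomes a contiguous token run.

Precedence is overlap expansion first, then discontinuous collapsing per
variant, with disjoint annotations carried unchanged into every variant.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ontogru import tokenization
from ontogru.datatypes import (
    SENTENCE_END_MARKS,
    SYNTHETIC_EOS_TOKEN,
    ArticleDocument,
    ConceptAnnotation,
    SentenceRecord,
    TaggedSentence,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "OverlapGroup",
    "segment_sentences",
    "group_annotations",
    "expand_variants",
    "collapse_discontinuous",
    "assign_iob",
    "preprocess_corpus",
    "SentenceRecord",
    "TaggedSentence",
]


@dataclass(frozen=True)
class OverlapGroup:
    """Mutually overlapping annotations; one alternative per distinct concept
    mention (nested sub-sub-phrases are flattened into the same group)."""

    alternatives: tuple[tuple[ConceptAnnotation, ...], ...]

    def __len__(self) -> int:
        return len(self.alternatives)


def segment_sentences(doc: ArticleDocument) -> list[SentenceRecord]:
    """Segment an article into tokenized sentences with absolute offsets."""
    records = []
    for idx, tokens in enumerate(tokenization.tokenize_sentences(doc.text)):
        if tokens:
            records.append(
                SentenceRecord(doc.article_id, idx, tuple(tokens))
            )
    return records


def _token_overlaps(token: tuple[str, int, int], span: tuple[int, int]) -> bool:
    # a token belongs to a span if their character ranges overlap at all
    return token[1] < span[1] and span[0] < token[2]


def _token_in_annotation(token, ann: ConceptAnnotation) -> bool:
    return any(_token_overlaps(token, span) for span in ann.spans)


def group_annotations(
    sentence: SentenceRecord, anns: Sequence[ConceptAnnotation]
) -> tuple[list[ConceptAnnotation], list[OverlapGroup], list[ConceptAnnotation]]:
    """Partition annotations into (disjoint, overlap groups, discontinuous).

    Annotations sharing any character range end up in the same overlap group
    regardless of span count; a non-overlapping multi-span annotation is
    discontinuous; everything else is disjoint.
    """
    anns = sorted(anns, key=lambda a: (a.start, a.end, a.concept_id))
    n = len(anns)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if anns[i].overlaps(anns[j]):
                parent[find(i)] = find(j)

    components: dict[int, list[ConceptAnnotation]] = {}
    for i, ann in enumerate(anns):
        components.setdefault(find(i), []).append(ann)

    disjoint: list[ConceptAnnotation] = []
    groups: list[OverlapGroup] = []
    discontinuous: list[ConceptAnnotation] = []
    for comp in components.values():
        if len(comp) >= 2:
            comp.sort(key=lambda a: (a.start, a.end, a.concept_id))
            groups.append(OverlapGroup(tuple((a,) for a in comp)))
        elif comp[0].discontinuous:
            discontinuous.append(comp[0])
        else:
            disjoint.append(comp[0])
    groups.sort(key=lambda g: g.alternatives[0][0].start)
    return disjoint, groups, discontinuous


def expand_variants(
    sentence: SentenceRecord,
    groups: Sequence[OverlapGroup],
    disjoint: Sequence[ConceptAnnotation],
    discontinuous: Sequence[ConceptAnnotation],
) -> list[tuple[SentenceRecord, list[ConceptAnnotation]]]:
    """Produce one sentence copy per combination of overlap alternatives.

    Exactly prod(n_i) variants are returned (one when there are no groups).
    In each variant the tokens covered only by non-chosen alternatives are
    removed, then discontinuous annotations (pre-existing or chosen) are
    collapsed; disjoint annotations appear unchanged in every variant.
    """
    variants: list[tuple[SentenceRecord, list[ConceptAnnotation]]] = []
    choice_lists = [g.alternatives for g in groups] or [((),)]
    for combo in itertools.product(*choice_lists):
        chosen: list[ConceptAnnotation] = [a for alt in combo for a in alt]
        kept = list(disjoint) + list(discontinuous) + chosen
        record = sentence
        # drop tokens that belong only to alternatives not chosen
        if groups:
            rejected_spans = [
                span
                for g, alt in zip(groups, combo)
                for alternative in g.alternatives
                if alternative != alt
                for a in alternative
                for span in a.spans
            ]
            new_tokens = tuple(
                tok
                for tok in record.tokens
                if any(_token_in_annotation(tok, a) for a in kept)
                or not any(_token_overlaps(tok, s) for s in rejected_spans)
            )
            record = SentenceRecord(record.article_id, record.sent_index, new_tokens)
        protect = [s for a in kept for s in a.spans]
        for ann in kept:
            if ann.discontinuous:
                record = collapse_discontinuous(
                    record, ann, protect=[s for s in protect if s not in ann.spans]
                )
        variants.append((record, sorted(kept, key=lambda a: (a.start, a.end))))
    return variants


def collapse_discontinuous(
    sentence: SentenceRecord,
    ann: ConceptAnnotation,
    protect: Sequence[tuple[int, int]] = (),
) -> SentenceRecord:
    """Delete the unannotated tokens between the spans of a discontinuous
    annotation so it becomes a contiguous token run.

    Tokens overlapping a span in ``protect`` (annotations that must survive)
    are kept.
    """
    first, last = ann.spans[0][0], ann.spans[-1][1]
    new_tokens = []
    for tok in sentence.tokens:
        inside_gap = (
            tok[1] >= first
            and tok[2] <= last
            and not _token_in_annotation(tok, ann)
        )
        if inside_gap and not any(_token_overlaps(tok, s) for s in protect):
            continue
        new_tokens.append(tok)
    return SentenceRecord(sentence.article_id, sentence.sent_index, tuple(new_tokens))


def assign_iob(
    sentence: SentenceRecord,
    anns: Sequence[ConceptAnnotation],
    variant_index: int = 0,
) -> TaggedSentence:
    """Tag each token B-/I-/O; the sentence-final mark gets the EOS tag.

    Annotations must be non-overlapping contiguous token runs at this stage
    (overlap expansion and discontinuous collapsing come first).  Sentences
    without terminal punctuation receive a synthetic terminal token so the
    EOS position always exists.
    """
    tokens = list(sentence.tokens)
    tags = ["O"] * len(tokens)
    for ann in anns:
        member_idx = [
            i for i, tok in enumerate(tokens) if _token_in_annotation(tok, ann)
        ]
        if not member_idx:
            log.warning(
                "%s sent %d: annotation %s matches no tokens",
                sentence.article_id, sentence.sent_index, ann.concept_id,
            )
            continue
        if member_idx != list(range(member_idx[0], member_idx[-1] + 1)):
            raise ValidationError(
                f"annotation {ann.concept_id} is not contiguous at IOB stage "
                "(expansion/collapsing must run first)"
            )
        if any(tags[i] != "O" for i in member_idx):
            raise ValidationError(
                f"annotation {ann.concept_id} overlaps another at IOB stage"
            )
        tags[member_idx[0]] = f"B-{ann.concept_id}"
        for i in member_idx[1:]:
            tags[i] = f"I-{ann.concept_id}"

    surfaces = [t[0] for t in tokens]
    if surfaces and surfaces[-1] in SENTENCE_END_MARKS:
        tags[-1] = "EOS"
    else:
        surfaces.append(SYNTHETIC_EOS_TOKEN)
        tags.append("EOS")
    return TaggedSentence(
        tokens=tuple(surfaces),
        tags=tuple(tags),
        provenance=(sentence.article_id, sentence.sent_index, variant_index),
    )


def transform_sentence(
    sentence: SentenceRecord, anns: Sequence[ConceptAnnotation]
) -> list[TaggedSentence]:
    """Full per-sentence pipeline: group -> expand -> collapse -> IOB."""
    disjoint, groups, discontinuous = group_annotations(sentence, anns)
    return [
        assign_iob(record, kept, variant_index=v)
        for v, (record, kept) in enumerate(
            expand_variants(sentence, groups, disjoint, discontinuous)
        )
    ]


def annotations_by_sentence(
    sentences: Sequence[SentenceRecord], anns: Sequence[ConceptAnnotation]
) -> list[list[ConceptAnnotation]]:
    """Route each annotation to the sentence containing its first span.

    Annotations crossing a sentence boundary are truncated to that sentence
    with a warning.
    """
    routed: list[list[ConceptAnnotation]] = [[] for _ in sentences]
    for ann in anns:
        target = None
        for i, sent in enumerate(sentences):
            if sent.start <= ann.start < sent.end:
                target = i
                break
        if target is None:
            log.warning("annotation %s falls outside all sentences", ann.concept_id)
            continue
        boundary = sentences[target].end
        if ann.end > boundary:
            clipped = tuple(
                (s, min(e, boundary)) for s, e in ann.spans if s < boundary
            )
            log.warning(
                "annotation %s crosses a sentence boundary; truncated",
                ann.concept_id,
            )
            ann = ConceptAnnotation(
                spans=clipped,
                spanned_text=ann.spanned_text,
                concept_id=ann.concept_id,
            )
        routed[target].append(ann)
    return routed


def split_articles(
    article_ids: Sequence[str], split_ratio: float, seed: int
) -> tuple[list[str], list[str]]:
    """Article-level train/test split: seeded shuffle, first ceil(r*N) train."""
    if not 0 < split_ratio < 1:
        raise ValueError(f"split_ratio must be in (0, 1), got {split_ratio}")
    if len(article_ids) < 2:
        raise ValueError("need at least 2 articles to split")
    rng = np.random.default_rng(seed)
    order = list(article_ids)
    rng.shuffle(order)
    n_train = math.ceil(split_ratio * len(order))
    return order[:n_train], order[n_train:]


def preprocess_article(
    doc: ArticleDocument, anns: Sequence[ConceptAnnotation]
) -> list[TaggedSentence]:
    """Segment one article and run the full transformation on each sentence."""
    sentences = segment_sentences(doc)
    routed = annotations_by_sentence(sentences, anns)
    out: list[TaggedSentence] = []
    for sent, sent_anns in zip(sentences, routed):
        out.extend(transform_sentence(sent, sent_anns))
    return out


def preprocess_corpus(
    articles: Sequence[ArticleDocument],
    annotations: Mapping[str, Sequence[ConceptAnnotation]],
    split_ratio: float = 0.8,
    seed: int = 0,
) -> tuple[list[TaggedSentence], list[TaggedSentence]]:
    """Article-level split followed by per-article preprocessing.

    Deterministic for a given seed; returns (train, test) sentence lists.
    """
    by_id = {doc.article_id: doc for doc in articles}
    train_ids, test_ids = split_articles(sorted(by_id), split_ratio, seed)
    train = [
        s
        for aid in train_ids
        for s in preprocess_article(by_id[aid], annotations.get(aid, ()))
    ]
    test = [
        s
        for aid in test_ids
        for s in preprocess_article(by_id[aid], annotations.get(aid, ()))
    ]
    return train, test
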