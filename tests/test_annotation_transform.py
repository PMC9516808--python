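"""Sentence segmentation, annotation grouping, variant expansion,
discontinuous collapsing and IOB assignment."""

import itertools

import pytest

from ontogru import annotation_transform as at
from ontogru import tokenization
from ontogru.datatypes import (
    ArticleDocument,
    ConceptAnnotation,
    ValidationError,
    concept_of,
    validate_iob,
)


def ann(text, phrase, cid, occurrence=0):
    start = -1
    for _ in range(occurrence + 1):
        start = text.index(phrase, start + 1)
    return ConceptAnnotation(((start, start + len(phrase)),), phrase, cid)


# -- segmentation and tokenization -----------------------------------------


def test_segment_published_sentence_tokens(examples):
    doc = ArticleDocument("ex", examples.iob[0].text)
    (sent,) = at.segment_sentences(doc)
    assert len(sent.tokens) == 15
    assert sent.surfaces[:5] == ("We", "observed", "a", "severe", "autosomal")
    assert sent.surfaces[-1] == "."


def test_segment_single_word_no_period():
    (sent,) = at.segment_sentences(ArticleDocument("ex", "Cytokinesis"))
    assert sent.surfaces == ("Cytokinesis",)


def test_segment_question_mark_boundary():
    doc = ArticleDocument("ex", "Is it true? We think so.")
    sents = at.segment_sentences(doc)
    assert len(sents) == 2
    assert sents[0].surfaces[-1] == "?"
    assert sents[1].surfaces[0] == "We"


def test_token_offsets_slice_back_to_surface(small_bundle):
    for doc in small_bundle.articles:
        for sent in at.segment_sentences(doc):
            for surface, start, end in sent.tokens:
                assert doc.text[start:end] == surface


# -- grouping ---------------------------------------------------------------


def test_group_disjoint_annotations(examples):
    we = examples.iob[3]  # anaphase / cytokinesis
    doc = ArticleDocument("ex", we.text)
    (sent,) = at.segment_sentences(doc)
    disjoint, groups, discont = at.group_annotations(sent, we.annotations)
    assert len(disjoint) == 2
    assert groups == []
    assert discont == []


def test_group_overlapping_pair_one_group(examples):
    we = examples.overlap_single
    doc = ArticleDocument("ex", we.text)
    (sent,) = at.segment_sentences(doc)
    disjoint, groups, discont = at.group_annotations(sent, we.annotations)
    assert disjoint == [] and discont == []
    assert len(groups) == 1
    assert len(groups[0]) == 2


def test_group_empty_input():
    doc = ArticleDocument("ex", "Nothing here.")
    (sent,) = at.segment_sentences(doc)
    assert at.group_annotations(sent, []) == ([], [], [])


def test_multispan_annotation_is_discontinuous(examples):
    we = examples.discontinuous
    doc = ArticleDocument("ex", we.text)
    (sent,) = at.segment_sentences(doc)
    disjoint, groups, discont = at.group_annotations(sent, we.annotations)
    assert len(discont) == 1 and disjoint == [] and groups == []


# -- variant expansion ------------------------------------------------------


@pytest.mark.parametrize("group_sizes", [(2,), (3,), (2, 2), (2, 3), (4, 2, 3)])
def test_variant_count_equals_cartesian_product(group_sizes):
    """|expand_variants| == prod(n_i), oracle = explicit product."""
    # build a synthetic sentence with one multi-word region per group
    words, anns_per_group = [], []
    text_parts = []
    pos = 0
    for g, n in enumerate(group_sizes):
        base = f"word{g}"
        ext = [f"ext{g}x{k}" for k in range(n - 1)]
        phrase_words = [base] + ext
        start = pos
        spans = []
        for w in phrase_words:
            spans.append((pos, pos + len(w)))
            text_parts.append(w)
            pos += len(w) + 1
        # alternatives: base alone, base+ext1, base+ext1+ext2, ...
        group = [
            ConceptAnnotation(((start, spans[k][1]),), "", f"GO:{g}-{k}")
            for k in range(n)
        ]
        anns_per_group.append(group)
    text_parts.append(".")
    text = " ".join(text_parts)
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    all_anns = [a for g in anns_per_group for a in g]
    disjoint, groups, discont = at.group_annotations(sent, all_anns)
    assert [len(g) for g in groups] == list(group_sizes)
    variants = at.expand_variants(sent, groups, disjoint, discont)
    expected = list(itertools.product(*[range(n) for n in group_sizes]))
    assert len(variants) == len(expected)
    # each variant realizes exactly one alternative per group
    combos = {
        tuple(sorted(a.concept_id for a in kept)) for _, kept in variants
    }
    assert len(combos) == len(expected)


def test_no_groups_single_identity_variant(examples):
    we = examples.iob[1]
    doc = ArticleDocument("ex", we.text)
    (sent,) = at.segment_sentences(doc)
    disjoint, groups, discont = at.group_annotations(sent, we.annotations)
    variants = at.expand_variants(sent, groups, disjoint, discont)
    assert len(variants) == 1
    assert variants[0][0] == sent


def test_disjoint_annotations_shared_across_variants():
    text = "We saw vesicle formation near anaphase today ."
    anns = [
        ann(text, "vesicle", "GO:A"),
        ann(text, "vesicle formation", "GO:B"),
        ann(text, "anaphase", "GO:C"),
    ]
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    disjoint, groups, discont = at.group_annotations(sent, anns)
    variants = at.expand_variants(sent, groups, disjoint, discont)
    assert len(variants) == 2
    for _, kept in variants:
        assert "GO:C" in {a.concept_id for a in kept}


# -- discontinuous collapsing ----------------------------------------------


def test_collapse_removes_gap_tokens(examples):
    we = examples.discontinuous
    doc = ArticleDocument("ex", we.text)
    (sent,) = at.segment_sentences(doc)
    collapsed = at.collapse_discontinuous(sent, we.annotations[0])
    assert "/p" not in collapsed.surfaces
    assert len(collapsed.tokens) == len(sent.tokens) - 1


def test_collapse_adjacent_spans_unchanged():
    text = "A big cell divides ."
    spans = (
        (text.index("big"), text.index("big") + 3),
        (text.index("cell"), text.index("cell") + 4),
    )
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    a = ConceptAnnotation(spans, "big cell", "GO:X")
    assert at.collapse_discontinuous(sent, a) == sent


def test_two_discontinuous_collapse_independently():
    text = "alpha /x beta gap gamma /y delta ."
    a1 = ConceptAnnotation(
        ((text.index("alpha"), 5), (text.index("beta"), text.index("beta") + 4)),
        "",
        "GO:A",
    )
    a2 = ConceptAnnotation(
        (
            (text.index("gamma"), text.index("gamma") + 5),
            (text.index("delta"), text.index("delta") + 5),
        ),
        "",
        "GO:B",
    )
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    # oracle: delete the union of unannotated between-span tokens
    expected = tuple(
        t for t in sent.surfaces if t not in ("/x", "/y")
    )
    result = sent
    for a in (a1, a2):
        result = at.collapse_discontinuous(result, a)
    assert result.surfaces == expected
    # "gap" lies between a1's spans? no — outside both annotations' gaps
    assert "gap" in result.surfaces


# -- IOB assignment ---------------------------------------------------------


def test_assign_iob_published_examples(examples):
    for we in examples.iob:
        doc = ArticleDocument("ex", we.text)
        produced = at.preprocess_article(doc, we.annotations)
        assert {(s.tokens, s.tags) for s in produced} == set(we.expected)


def test_assign_iob_conserves_token_count():
    text = "The spindle moved ."
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    tagged = at.assign_iob(sent, [ann(text, "spindle", "GO:S")])
    assert len(tagged.tokens) == len(sent.tokens)  # '.' present, no synthetic
    assert tagged.tags[-1] == "EOS"


def test_assign_iob_overlapping_runs_rejected():
    text = "vesicle formation here ."
    doc = ArticleDocument("ex", text)
    (sent,) = at.segment_sentences(doc)
    with pytest.raises(ValidationError):
        at.assign_iob(
            sent,
            [ann(text, "vesicle", "GO:A"), ann(text, "vesicle formation", "GO:B")],
        )


def test_annotation_recoverable_from_tags(small_bundle):
    """Decoding B/I runs recovers the concept token runs fed in."""
    for doc in small_bundle.articles:
        anns = small_bundle.annotations[doc.article_id]
        sentences = at.segment_sentences(doc)
        routed = at.annotations_by_sentence(sentences, anns)
        for sent, sent_anns in zip(sentences, routed):
            disjoint, groups, discont = at.group_annotations(sent, sent_anns)
            for v, (record, kept) in enumerate(
                at.expand_variants(sent, groups, disjoint, discont)
            ):
                tagged = at.assign_iob(record, kept, v)
                validate_iob(tagged.tags)
                decoded = []
                for tag in tagged.tags:
                    if tag.startswith("B-"):
                        decoded.append(concept_of(tag))
                assert sorted(decoded) == sorted(a.concept_id for a in kept)


def test_iob_well_formed_across_generated_corpus(small_bundle):
    for sent in small_bundle.truth:
        validate_iob(sent.tags)
        assert sum(t == "EOS" for t in sent.tags) == 1


# -- corpus-level preprocessing --------------------------------------------


def test_split_deterministic_and_sized():
    ids = [f"a{i}" for i in range(10)]
    train1, test1 = at.split_articles(ids, 0.8, seed=7)
    train2, test2 = at.split_articles(ids, 0.8, seed=7)
    assert (train1, test1) == (train2, test2)
    assert len(train1) == 8 and len(test1) == 2


def test_split_craft_article_count_rule():
    ids = [f"a{i}" for i in range(97)]
    train, test = at.split_articles(ids, 0.8, seed=0)
    assert len(train) == 78 and len(test) == 19


def test_split_requires_two_articles():
    with pytest.raises(ValueError):
        at.split_articles(["only"], 0.8, seed=0)
    with pytest.raises(ValueError):
        at.split_articles(["a", "b"], 1.5, seed=0)


def test_preprocess_corpus_deterministic(small_bundle):
    run1 = at.preprocess_corpus(
        small_bundle.articles, small_bundle.annotations, 0.8, seed=7
    )
    run2 = at.preprocess_corpus(
        small_bundle.articles, small_bundle.annotations, 0.8, seed=7
    )
    assert run1 == run2
    train, test = run1
    train_ids = {s.provenance[0] for s in train}
    test_ids = {s.provenance[0] for s in test}
    assert not train_ids & test_ids  # article-level split


def test_boundary_crossing_annotation_truncated(caplog):
    import logging

    text = "First ends here. Second one follows."
    doc = ArticleDocument("ex", text)
    sents = at.segment_sentences(doc)
    crossing = ConceptAnnotation(
        ((text.index("here"), text.index("Second") + 6),), "", "GO:Z"
    )
    with caplog.at_level(logging.WARNING):
        routed = at.annotations_by_sentence(sents, [crossing])
    assert len(routed[0]) == 1
    assert routed[0][0].end <= sents[0].end
    assert any("boundary" in r.message for r in caplog.records)
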