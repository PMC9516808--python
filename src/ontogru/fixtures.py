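"""Seeded synthetic corpora, toy ontologies and lexicons for offline testing,
plus the bundled worked examples used as literal regression fixtures.

The generator emulates a CRAFT-style corpus: plain-text articles whose
sentences embed concept mention phrases at exactly known character offsets,
with controllable fractions of overlapping, multiply-overlapping and
discontinuous annotations, and a Zipf-skewed concept frequency distribution
so frequency-binned evaluation is exercisable.  Generation is a pure
function of the spec (same spec -> byte-identical corpus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ontogru.corpus_io import write_conll
from ontogru.datatypes import (
    ArticleDocument,
    ConceptAnnotation,
    LexiconTable,
    OntologyGraph,
    TaggedSentence,
)
from ontogru.feature_encoders import BIOTHESAURUS_CATEGORIES

__all__ = [
    "FixtureSpec",
    "CorpusBundle",
    "generate_ontology",
    "generate_corpus",
    "write_obo",
    "paper_examples",
]

_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")

# word banks; mention words never collide with template words so synthetic
# corpora are separable (each mention token determines its concept)
_MENTION_WORDS = [
    "vesicle", "anaphase", "cytokinesis", "apoptosis", "ribosome", "kinase",
    "chromatin", "autophagy", "glycolysis", "mitosis", "telomere", "lysosome",
    "exocytosis", "meiosis", "proteolysis", "spindle", "nucleolus", "axon",
    "dendrite", "synapse", "cilium", "flagellum", "peroxisome", "endosome",
    "centriole", "kinetochore", "cohesin", "septin", "lamin", "tubulin",
    "actin", "myosin", "integrin", "cadherin", "laminin", "fibronectin",
    "collagen", "elastin", "keratin", "vimentin",
]
_EXTENSION_WORDS = [
    "formation", "fusion", "assembly", "transport", "binding", "signaling",
    "maturation", "elongation", "remodeling", "segregation", "biogenesis",
    "turnover", "docking", "budding", "sorting", "tethering", "priming",
    "recycling", "clustering", "disassembly",
]

_PLAIN_PREFIXES = [
    ["We", "observed"],
    ["The", "cells", "showed"],
    ["Loss", "of", "function", "affected"],
    ["These", "results", "implicate"],
    ["Histology", "revealed"],
]
_PLAIN_SUFFIXES = [
    ["in", "mutant", "mice", "."],
    ["in", "all", "samples", "."],
    ["during", "early", "development", "."],
    ["under", "stress", "conditions", "."],
]
_EMPTY_SENTENCES = [
    ["No", "differences", "were", "found", "between", "groups", "."],
    ["Experiments", "were", "performed", "twice", "."],
    ["Data", "are", "shown", "with", "standard", "errors", "."],
    ["Animals", "were", "housed", "under", "standard", "conditions", "."],
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus; generation is deterministic."""

    n_articles: int = 10
    sentences_per_article: tuple[int, int] = (8, 15)
    n_concepts: int = 10
    ontology_depth: int = 3
    p_overlap: float = 0.1
    p_discontinuous: float = 0.05
    p_multi_overlap: float = 0.02
    p_no_annotation: float = 0.2
    zipf_exponent: float = 2.0  # CRAFT-like skew: most of the concept
    # inventory is low-frequency, with the tail seen only once or twice
    seed: int = 0
    misaligned: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_overlap, self.p_discontinuous, self.p_multi_overlap,
                  self.p_no_annotation):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_articles < 1 or self.n_concepts < 1:
            raise ValueError("counts must be >= 1")
        if self.p_multi_overlap > 0 and self.n_concepts < 4:
            raise ValueError("multiply-overlapping sentences need >= 4 concepts")
        if (self.p_overlap > 0 or self.p_multi_overlap > 0) and self.n_concepts < 2:
            raise ValueError("overlapping sentences need >= 2 concepts")


def _concept_id(rank: int) -> str:
    return f"GO:{rank + 1:07d}"


def generate_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, str]:
    """Rooted DAG with three namespace subtrees (BP/CC/MF analogues).

    Concept ranks are assigned round-robin to the namespaces; each non-root
    term has one or two parents within its namespace, at depth at most
    ``spec.ontology_depth`` below the namespace root.
    """
    rng = np.random.default_rng(spec.seed)
    n_roots = min(3, spec.n_concepts)
    concepts, name, parents, namespace = [], {}, {}, {}
    depth: dict[str, int] = {}
    by_ns: dict[str, list[str]] = {ns: [] for ns in _NAMESPACES}
    for rank in range(spec.n_concepts):
        cid = _concept_id(rank)
        ns = _NAMESPACES[rank % 3]
        concepts.append(cid)
        name[cid] = f"concept {rank + 1}"
        namespace[cid] = ns
        if rank < n_roots:
            parents[cid] = set()
            depth[cid] = 0
        else:
            pool = [c for c in by_ns[ns] if depth[c] < spec.ontology_depth]
            if not pool:  # subtree saturated: hang off its shallowest node
                pool = [min(by_ns[ns], key=lambda c: depth[c])]
            n_par = 1 if len(pool) == 1 or rng.random() < 0.7 else 2
            chosen = list(rng.choice(pool, size=n_par, replace=False))
            parents[cid] = set(chosen)
            depth[cid] = 1 + max(depth[p] for p in chosen)
        by_ns[ns].append(cid)
    onto = OntologyGraph(concepts, name, parents, namespace)
    return onto, write_obo(onto)


def write_obo(onto: OntologyGraph) -> str:
    """Serialize an OntologyGraph as an OBO 1.2 document."""
    lines = ["format-version: 1.2", ""]
    for cid in sorted(onto.concepts):
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {onto.name.get(cid, cid)}")
        ns = onto.namespace.get(cid)
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(onto.parents.get(cid, ())):
            lines.append(f"is_a: {parent} ! {onto.name.get(parent, parent)}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class CorpusBundle:
    """Everything the generator knows about one synthetic corpus."""

    spec: FixtureSpec
    ontology: OntologyGraph
    obo_text: str
    articles: list[ArticleDocument]
    annotations: dict[str, list[ConceptAnnotation]]
    xml: dict[str, str]
    truth: list[TaggedSentence]
    concept_phrases: dict[str, tuple[str, ...]]
    biothesaurus: LexiconTable
    umls: LexiconTable
    sentence_kinds: dict[str, int] = field(default_factory=dict)
    concept_mentions: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write articles/, xml/, ontology.obo, lexicons/ and truth.tsv."""
        out = Path(out_dir)
        (out / "articles").mkdir(parents=True, exist_ok=True)
        (out / "xml").mkdir(exist_ok=True)
        (out / "lexicons").mkdir(exist_ok=True)
        for doc in self.articles:
            (out / "articles" / f"{doc.article_id}.txt").write_text(
                doc.text, encoding="utf-8"
            )
            (out / "xml" / f"{doc.article_id}.xml").write_text(
                self.xml[doc.article_id], encoding="utf-8"
            )
        (out / "ontology.obo").write_text(self.obo_text, encoding="utf-8")
        for lex_name, lex in (("biothesaurus", self.biothesaurus), ("umls", self.umls)):
            rows = [
                "\t".join([surface, *map(str, flags)])
                for surface, flags in sorted(lex.entries.items())
            ]
            (out / "lexicons" / f"{lex_name}.tsv").write_text(
                "\n".join(rows) + "\n", encoding="utf-8"
            )
        write_conll(self.truth, out / "truth.tsv")


def _assign_phrases(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """Unique mention phrase per concept.

    When overlaps are enabled, each odd-ranked concept's phrase extends the
    preceding even-ranked concept's phrase by one word, giving natural
    sub-phrase annotation pairs.
    """
    heads = list(rng.permutation(_MENTION_WORDS))[: spec.n_concepts]
    exts = list(rng.permutation(_EXTENSION_WORDS))
    phrases: dict[str, tuple[str, ...]] = {}
    pairing = spec.p_overlap > 0 or spec.p_multi_overlap > 0
    for rank in range(spec.n_concepts):
        cid = _concept_id(rank)
        if pairing and rank % 2 == 1:
            phrases[cid] = phrases[_concept_id(rank - 1)] + (exts[rank // 2],)
        elif not pairing and rank % 3 == 2:
            phrases[cid] = (heads[rank], exts[rank % len(exts)])
        else:
            phrases[cid] = (heads[rank],)
    return phrases


class _SentenceBuilder:
    """Accumulates tokens with running character offsets."""

    def __init__(self, offset: int):
        self.tokens: list[tuple[str, int, int]] = []
        self.pos = offset

    def add(self, words: Sequence[str]) -> list[tuple[int, int]]:
        spans = []
        for w in words:
            start = self.pos
            end = start + len(w)
            self.tokens.append((w, start, end))
            spans.append((start, end))
            self.pos = end + 1  # single space separator
        return spans

    @property
    def text(self) -> str:
        return " ".join(t[0] for t in self.tokens)


class _ZipfSampler:
    """Zipf-weighted concept sampling for disjoint mentions.

    Sampling is i.i.d., so a tiny corpus shows natural starvation: some
    tail concepts receive only one or two mentions, as in real corpora.
    """

    def __init__(self, n_ranks: int, exponent: float):
        weights = np.array([1.0 / (r + 1) ** exponent for r in range(n_ranks)])
        self.shares = weights / weights.sum()
        self.ranks = np.arange(n_ranks)

    def pick(self, rng, exclude: set[int] = frozenset()) -> int:
        p = self.shares.copy()
        for r in exclude:
            p[r] = 0.0
        return int(rng.choice(self.ranks, p=p / p.sum()))


def generate_corpus(spec: FixtureSpec, onto: OntologyGraph | None = None) -> CorpusBundle:
    """Generate articles, annotation XML, lexicons and ground truth.

    With an internally generated ontology, concept ids are assigned so that
    id order equals realized mention-frequency order (rank 1 = most
    frequent); a caller-supplied ontology is used verbatim.
    """
    generated_onto = onto is None
    if generated_onto:
        onto, obo_text = generate_ontology(spec)
    else:
        obo_text = write_obo(onto)
    rng = np.random.default_rng(spec.seed + 1)
    phrases = _assign_phrases(spec, rng)
    pairing = spec.p_overlap > 0 or spec.p_multi_overlap > 0
    even_ranks = [r for r in range(0, spec.n_concepts - 1, 2)]
    multi_word_ranks = [
        r for r in range(spec.n_concepts) if len(phrases[_concept_id(r)]) >= 2
    ]
    alloc = _ZipfSampler(spec.n_concepts, spec.zipf_exponent)

    articles: list[ArticleDocument] = []
    annotations: dict[str, list[ConceptAnnotation]] = {}
    xml: dict[str, str] = {}
    truth: list[TaggedSentence] = []
    kinds = {"disjoint": 0, "overlap": 0, "multi_overlap": 0,
             "discontinuous": 0, "none": 0}
    mentions: dict[str, int] = {}

    for art_i in range(spec.n_articles):
        article_id = f"synth{art_i:03d}"
        lo, hi = spec.sentences_per_article
        n_sent = int(rng.integers(lo, hi + 1))
        text_parts: list[str] = []
        offset = 0
        art_anns: list[ConceptAnnotation] = []
        for sent_i in range(n_sent):
            builder = _SentenceBuilder(offset)
            u = rng.random()
            if pairing and u < spec.p_multi_overlap and len(even_ranks) >= 2:
                kind = "multi_overlap"
            elif pairing and u < spec.p_multi_overlap + spec.p_overlap:
                kind = "overlap"
            elif (
                multi_word_ranks
                and u < spec.p_multi_overlap + spec.p_overlap + spec.p_discontinuous
            ):
                kind = "discontinuous"
            elif rng.random() < spec.p_no_annotation:
                kind = "none"
            else:
                kind = "disjoint"
            kinds[kind] += 1
            sent_anns, sent_truth = _build_sentence(
                builder, kind, spec, rng, phrases, even_ranks, alloc,
                multi_word_ranks, article_id, sent_i, mentions,
            )
            art_anns.extend(sent_anns)
            truth.extend(sent_truth)
            text_parts.append(builder.text)
            offset = builder.pos  # builder already accounts for the joiner
        doc = ArticleDocument(article_id, " ".join(text_parts))
        articles.append(doc)
        annotations[article_id] = art_anns

    if generated_onto:
        # rank concept ids by realized frequency so id order == frequency
        # order (i.i.d. sampling alone cannot guarantee monotone counts)
        remap = _frequency_remap(spec.n_concepts, mentions)
        onto = _remap_ontology(onto, remap)
        obo_text = write_obo(onto)
        phrases = {remap[c]: w for c, w in phrases.items()}
        mentions = {remap[c]: n for c, n in mentions.items()}
        annotations = {
            aid: [
                ConceptAnnotation(a.spans, a.spanned_text, remap[a.concept_id])
                for a in anns
            ]
            for aid, anns in annotations.items()
        }
        truth = [_remap_tags(s, remap) for s in truth]

    xml = {
        aid: _annotations_to_xml(aid, anns) for aid, anns in annotations.items()
    }
    biot, umls = _build_lexicons(spec, rng, phrases)
    return CorpusBundle(
        spec=spec,
        ontology=onto,
        obo_text=obo_text,
        articles=articles,
        annotations=annotations,
        xml=xml,
        truth=truth,
        concept_phrases=phrases,
        biothesaurus=biot,
        umls=umls,
        sentence_kinds=kinds,
        concept_mentions=mentions,
    )


def _record_mention(mentions: dict[str, int], cid: str, n_tokens: int) -> None:
    # one occurrence per mention, regardless of phrase length
    mentions[cid] = mentions.get(cid, 0) + 1


def _tags_for(tokens, spans_by_concept) -> tuple[str, ...]:
    """IOB tags for contiguous token runs given per-concept token spans."""
    tags = ["O"] * len(tokens)
    for cid, idxs in spans_by_concept:
        tags[idxs[0]] = f"B-{cid}"
        for i in idxs[1:]:
            tags[i] = f"I-{cid}"
    tags[-1] = "EOS"
    return tuple(tags)


def _build_sentence(
    builder, kind, spec, rng, phrases, even_ranks, alloc,
    multi_word_ranks, article_id, sent_i, mentions,
):
    """Emit one sentence into the builder; return (annotations, truth)."""
    anns: list[ConceptAnnotation] = []
    prefix = _PLAIN_PREFIXES[int(rng.integers(len(_PLAIN_PREFIXES)))]
    suffix = _PLAIN_SUFFIXES[int(rng.integers(len(_PLAIN_SUFFIXES)))]

    if kind == "none":
        words = _EMPTY_SENTENCES[int(rng.integers(len(_EMPTY_SENTENCES)))]
        builder.add(words)
        surfaces = tuple(w for w, *_ in builder.tokens)
        return anns, [
            TaggedSentence(surfaces, _tags_for(surfaces, []), (article_id, sent_i, 0))
        ]

    if kind == "disjoint":
        n_mentions = 1 if rng.random() < 0.6 else min(2, spec.n_concepts)
        chosen: list[int] = []
        while len(chosen) < n_mentions:
            chosen.append(alloc.pick(rng, exclude=set(chosen)))
        builder.add(prefix)
        runs = []
        for j, r in enumerate(chosen):
            cid = _concept_id(r)
            words = phrases[cid]
            start_idx = len(builder.tokens)
            spans = builder.add(words)
            runs.append((cid, list(range(start_idx, start_idx + len(words)))))
            anns.append(_make_ann(spans, words, cid, spec, contiguous=True))
            _record_mention(mentions, cid, len(words))
            if j < len(chosen) - 1:
                builder.add(["and"])
        builder.add(suffix)
        surfaces = tuple(w for w, *_ in builder.tokens)
        return anns, [
            TaggedSentence(surfaces, _tags_for(surfaces, runs), (article_id, sent_i, 0))
        ]

    if kind == "discontinuous":
        r = multi_word_ranks[int(rng.integers(len(multi_word_ranks)))]
        cid = _concept_id(r)
        w1, *rest = phrases[cid]
        builder.add(prefix)
        first_idx = len(builder.tokens)
        span1 = builder.add([w1])
        builder.add(["/f"])  # unannotated filler interrupting the phrase
        rest_idx = len(builder.tokens)
        span2 = builder.add(list(rest))
        builder.add(suffix)
        anns.append(
            ConceptAnnotation(
                spans=(span1[0], (span2[0][0], span2[-1][1])),
                spanned_text=f"{w1} ... {' '.join(rest)}",
                concept_id=cid,
            )
        )
        _record_mention(mentions, cid, len(phrases[cid]))
        # truth: filler removed, phrase contiguous
        kept = [t for i, t in enumerate(builder.tokens) if i != first_idx + 1]
        surfaces = tuple(w for w, *_ in kept)
        idxs = list(range(first_idx, first_idx + len(phrases[cid])))
        return anns, [
            TaggedSentence(
                surfaces, _tags_for(surfaces, [(cid, idxs)]), (article_id, sent_i, 0)
            )
        ]

    # overlap kinds: each group embeds the extended phrase of an odd-ranked
    # concept; the even-ranked prefix concept is the sub-phrase alternative
    n_groups = 2 if kind == "multi_overlap" else 1
    group_ranks = [int(r) for r in rng.choice(even_ranks, size=n_groups, replace=False)]
    builder.add(prefix)
    groups = []  # (cid_short, cid_long, token_idxs_short, token_idx_ext)
    for j, r in enumerate(group_ranks):
        c_short, c_long = _concept_id(r), _concept_id(r + 1)
        words_long = phrases[c_long]
        start_idx = len(builder.tokens)
        spans = builder.add(words_long)
        n_short = len(phrases[c_short])
        short_span = (spans[0][0], spans[n_short - 1][1])
        long_span = (spans[0][0], spans[-1][1])
        anns.append(
            _make_ann([short_span], phrases[c_short], c_short, spec, contiguous=True)
        )
        anns.append(
            _make_ann([long_span], words_long, c_long, spec, contiguous=True)
        )
        _record_mention(mentions, c_short, n_short)
        _record_mention(mentions, c_long, len(words_long))
        groups.append(
            (c_short, c_long, list(range(start_idx, start_idx + len(words_long))), n_short)
        )
        if j < n_groups - 1:
            builder.add(["and"])
    builder.add(suffix)

    # truth variants: Cartesian product, short alternative first in each group
    surfaces_full = [w for w, *_ in builder.tokens]
    variant_truth = []
    import itertools

    for v, combo in enumerate(itertools.product(*[("short", "long")] * n_groups)):
        drop: set[int] = set()
        runs = []
        for (c_short, c_long, idxs, n_short), choice in zip(groups, combo):
            if choice == "short":
                drop.update(idxs[n_short:])
                runs.append((c_short, idxs[:n_short]))
            else:
                runs.append((c_long, idxs))
        kept_idx = [i for i in range(len(surfaces_full)) if i not in drop]
        remap = {old: new for new, old in enumerate(kept_idx)}
        surfaces = tuple(surfaces_full[i] for i in kept_idx)
        runs = [(cid, [remap[i] for i in idxs]) for cid, idxs in runs]
        variant_truth.append(
            TaggedSentence(
                surfaces, _tags_for(surfaces, runs), (article_id, sent_i, v)
            )
        )
    return anns, variant_truth


def _frequency_remap(n_concepts: int, mentions: dict[str, int]) -> dict[str, str]:
    old_ids = [_concept_id(r) for r in range(n_concepts)]
    ranked = sorted(old_ids, key=lambda c: (-mentions.get(c, 0), c))
    return {old: _concept_id(rank) for rank, old in enumerate(ranked)}


def _remap_ontology(onto: OntologyGraph, remap: dict[str, str]) -> OntologyGraph:
    return OntologyGraph(
        [remap[c] for c in onto.concepts],
        {remap[c]: onto.name[c] for c in onto.concepts},
        {remap[c]: {remap[p] for p in ps} for c, ps in onto.parents.items()},
        {remap[c]: onto.namespace[c] for c in onto.concepts},
    )


def _remap_tags(sent: TaggedSentence, remap: dict[str, str]) -> TaggedSentence:
    tags = tuple(
        t[:2] + remap[t[2:]] if t[:2] in ("B-", "I-") else t for t in sent.tags
    )
    return TaggedSentence(sent.tokens, tags, sent.provenance)


def _make_ann(spans, words, cid, spec, contiguous):
    start, end = spans[0][0], spans[-1][1]
    if spec.misaligned and end - start > 2:
        start += 1  # off-by-one span: exercises the token-overlap rule
    return ConceptAnnotation(
        spans=((start, end),), spanned_text=" ".join(words), concept_id=cid
    )


def _annotations_to_xml(article_id: str, anns: Sequence[ConceptAnnotation]) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<annotations textSource="{article_id}">',
    ]
    for i, ann in enumerate(anns):
        lines.append(f'  <annotation id="a{i}">')
        lines.append(f'    <class id="{ann.concept_id}"/>')
        for s, e in ann.spans:
            lines.append(f'    <span start="{s}" end="{e}"/>')
        lines.append(f"    <spannedText>{ann.spanned_text}</spannedText>")
        lines.append("  </annotation>")
    lines.append("</annotations>")
    return "\n".join(lines) + "\n"


def _build_lexicons(spec, rng, phrases) -> tuple[LexiconTable, LexiconTable]:
    """Toy BioThesaurus/UMLS stand-ins covering the mention vocabulary."""
    biot_entries: dict[str, tuple[int, ...]] = {}
    umls_entries: dict[str, tuple[int, ...]] = {}
    for cid, words in sorted(phrases.items()):
        for w in words:
            if w not in biot_entries:
                flags = tuple(int(rng.random() < p) for p in (0.6, 0.4, 0.15, 0.1))
                if any(flags):
                    biot_entries[w] = flags
        if rng.random() < 0.7:
            umls_entries[" ".join(words)] = (1,)
    for w in ("mutant", "mice", "cells", "stress"):
        if rng.random() < 0.5:
            umls_entries[w] = (1,)
    return (
        LexiconTable(biot_entries, BIOTHESAURUS_CATEGORIES, max_phrase_len=1),
        LexiconTable(umls_entries, ("umls",), max_phrase_len=5),
    )


# ---------------------------------------------------------------------------
# Bundled worked examples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExample:
    """A sentence with annotations and its expected IOB variant(s)."""

    name: str
    text: str
    annotations: tuple[ConceptAnnotation, ...]
    expected: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (tokens, tags)


@dataclass(frozen=True)
class PaperExamples:
    """The worked preprocessing examples bundled as literal fixtures."""

    iob: tuple[WorkedExample, ...]
    overlap_single: WorkedExample
    overlap_multi: WorkedExample
    discontinuous: WorkedExample
    annotation_xml: tuple[str, str, ConceptAnnotation]  # (article text, xml, expected)
    char_repr: dict[str, str]
    pos_tokens: tuple[str, ...]
    pos_tags: tuple[str, ...]
    lexicon_tokens: tuple[str, ...]
    biothesaurus_lexicon: LexiconTable
    biothesaurus_flags: tuple[tuple[int, int, int, int], ...]
    umls_lexicon: LexiconTable
    umls_flags: tuple[int, ...]


def _span_of(text: str, phrase: str) -> tuple[int, int]:
    start = text.index(phrase)
    return start, start + len(phrase)


def _ann(text: str, phrase: str, cid: str) -> ConceptAnnotation:
    return ConceptAnnotation((_span_of(text, phrase),), phrase, cid)


def paper_examples() -> PaperExamples:
    """Build the bundle of in-text worked examples."""
    # -- simple IOB sentences ------------------------------------------------
    autosomal_text = (
        "We observed a severe autosomal recessive movement disorder in mice "
        "used within our laboratory."
    )
    autosomal = WorkedExample(
        "autosomal",
        autosomal_text,
        (_ann(autosomal_text, "autosomal", "GO:0030849"),),
        ((
            tuple(
                "We observed a severe autosomal recessive movement disorder "
                "in mice used within our laboratory".split()
            ) + (".",),
            ("O",) * 4 + ("B-GO:0030849",) + ("O",) * 9 + ("EOS",),
        ),),
    )

    apoptotic_text = (
        "The phosphatidylserine receptor primarily functions in apoptotic "
        "cell clearance."
    )
    apoptotic = WorkedExample(
        "apoptotic",
        apoptotic_text,
        (_ann(apoptotic_text, "apoptotic cell clearance", "GO:0043277"),),
        ((
            tuple(
                "The phosphatidylserine receptor primarily functions in "
                "apoptotic cell clearance".split()
            ) + (".",),
            ("O",) * 6
            + ("B-GO:0043277", "I-GO:0043277", "I-GO:0043277", "EOS"),
        ),),
    )

    rescue_text = (
        "Rescue of Progeria in Trichothiodystrophy by Homozygous Lethal Xpd "
        "Alleles"
    )
    rescue = WorkedExample(
        "rescue_title",
        rescue_text,
        (),
        ((
            tuple(rescue_text.split()) + ("<EOS>",),
            ("O",) * 10 + ("EOS",),
        ),),
    )

    anaphase_text = (
        "A cell progressing from anaphase to cytokinesis (pink arrowheads)."
    )
    anaphase = WorkedExample(
        "anaphase_cytokinesis",
        anaphase_text,
        (
            _ann(anaphase_text, "anaphase", "GO:0051322"),
            _ann(anaphase_text, "cytokinesis", "GO:0000910"),
        ),
        ((
            ("A", "cell", "progressing", "from", "anaphase", "to",
             "cytokinesis", "(", "pink", "arrowheads", ")", "."),
            ("O", "O", "O", "O", "B-GO:0051322", "O", "B-GO:0000910",
             "O", "O", "O", "O", "EOS"),
        ),),
    )

    # -- overlap expansion ---------------------------------------------------
    base = (
        "Having excluded a direct role in vesicle formation and membrane "
        "fusion, annexin A7 might act by its property as Ca2+-binding protein"
    )
    tail_tokens = (
        "annexin", "A7", "might", "act", "by", "its", "property", "as",
        "Ca2+-binding", "protein",
    )
    head_tokens = ("Having", "excluded", "a", "direct", "role", "in")

    def _variant(mid_tokens: tuple[str, ...], runs) -> tuple[tuple[str, ...], tuple[str, ...]]:
        tokens = head_tokens + mid_tokens + (",",) + tail_tokens + ("<EOS>",)
        tags = ["O"] * len(tokens)
        for cid, idxs in runs:
            tags[idxs[0]] = f"B-{cid}"
            for i in idxs[1:]:
                tags[i] = f"I-{cid}"
        tags[-1] = "EOS"
        return tokens, tuple(tags)

    overlap_single = WorkedExample(
        "vesicle_overlap",
        base,
        (
            _ann(base, "vesicle", "GO:0031982"),
            _ann(base, "vesicle formation", "GO:0006900"),
        ),
        (
            # chosen: 'vesicle' -> 'formation' removed
            _variant(("vesicle", "and", "membrane", "fusion"),
                     [("GO:0031982", [6])]),
            # chosen: 'vesicle formation'
            _variant(("vesicle", "formation", "and", "membrane", "fusion"),
                     [("GO:0006900", [6, 7])]),
        ),
    )

    multi_text = base + "."
    overlap_multi = WorkedExample(
        "vesicle_membrane_multi_overlap",
        multi_text,
        (
            _ann(multi_text, "vesicle", "GO:0031982"),
            _ann(multi_text, "vesicle formation", "GO:0006900"),
            _ann(multi_text, "membrane", "GO:0016020"),
            _ann(multi_text, "membrane fusion", "GO:0061025"),
        ),
        tuple(
            _variant_multi(head_tokens, tail_tokens, v1, v2)
            for v1 in ("short", "long")
            for v2 in ("short", "long")
        ),
    )

    disc_text = (
        "Because the F7 is the most severely affected allele, it is possible "
        "that the difference between the heart and kidney levels is due to a "
        "developmental delay in v/p formation."
    )
    v_start = disc_text.index(" v/p ") + 1
    formation_span = _span_of(disc_text, "formation")
    disc_tokens_collapsed = (
        "Because", "the", "F7", "is", "the", "most", "severely", "affected",
        "allele", ",", "it", "is", "possible", "that", "the", "difference",
        "between", "the", "heart", "and", "kidney", "levels", "is", "due",
        "to", "a", "developmental", "delay", "in", "v", "formation", ".",
    )
    discontinuous = WorkedExample(
        "v_formation_discontinuous",
        disc_text,
        (
            ConceptAnnotation(
                spans=((v_start, v_start + 1), formation_span),
                spanned_text="v ... formation",
                concept_id="GO:0097084",
            ),
        ),
        ((
            disc_tokens_collapsed,
            ("O",) * 29 + ("B-GO:0097084", "I-GO:0097084", "EOS"),
        ),),
    )

    # -- annotation XML with the published character offsets ------------------
    pad = "This opening sentence exists only to pad the character offsets."
    pad = pad + " " * (94 - len(pad) - 1) + " "  # 'We' starts at offset 94
    xml_article = pad + autosomal_text
    assert xml_article[115:124] == "autosomal"
    xml_string = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<annotations textSource="ex">\n'
        '  <annotation id="a0">\n'
        '    <class id="GO:0030849"/>\n'
        '    <span start="115" end="124"/>\n'
        "    <spannedText>autosomal</spannedText>\n"
        "  </annotation>\n"
        "</annotations>\n"
    )
    xml_expected = ConceptAnnotation(((115, 124),), "autosomal", "GO:0030849")

    # -- character representation and POS -------------------------------------
    char_repr = {
        "Smith-Lemli-Opitz": "Ccc-Ccc-Ccc",
        "syndrome": "ccc",
        "(": "(",
        "SLOS": "CCC",
        ",": ",",
        "MIM": "CCC",
        "270400": "N",
        ")": ")",
        "a": "c",
        "is": "cc",
        "DHCR7": "CCCN",
        "[": "[",
        "2-5": "N-N",
        "]": "]",
        "∇": "U",
    }
    pos_tokens = ("Smith-Lemli-Opitz", "syndrome", "(", "SLOS", ",")
    pos_tags = ("NNP", "NN", "-LRB-", "NNP", ",")

    # -- BioThesaurus / UMLS ---------------------------------------------------
    lexicon_tokens = (
        "Hematopoiesis", "is", "precisely", "orchestrated", "by",
        "lineage-specific", "DNA-binding", "proteins", "that", "regulate",
        "transcription", "in", "concert", "with", "coactivators", "and",
        "corepressors", ".",
    )
    protein = (0, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 1, 0, 0, 0, 1, 0, 0)
    biomedical = (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0)
    biot_entries = {}
    for tok, p_flag, b_flag in zip(lexicon_tokens, protein, biomedical):
        if p_flag or b_flag:
            biot_entries[tok.lower()] = (p_flag, b_flag, 0, 0)
    biothesaurus_lexicon = LexiconTable(
        biot_entries, BIOTHESAURUS_CATEGORIES, max_phrase_len=1
    )
    biothesaurus_flags = tuple(
        (p, b, 0, 0) for p, b in zip(protein, biomedical)
    )
    umls_flags = (1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0)
    umls_lexicon = LexiconTable(
        {tok.lower(): (1,) for tok, f in zip(lexicon_tokens, umls_flags) if f},
        ("umls",),
        max_phrase_len=5,
    )

    return PaperExamples(
        iob=(autosomal, apoptotic, rescue, anaphase, discontinuous),
        overlap_single=overlap_single,
        overlap_multi=overlap_multi,
        discontinuous=discontinuous,
        annotation_xml=(xml_article, xml_string, xml_expected),
        char_repr=char_repr,
        pos_tokens=pos_tokens,
        pos_tags=pos_tags,
        lexicon_tokens=lexicon_tokens,
        biothesaurus_lexicon=biothesaurus_lexicon,
        biothesaurus_flags=biothesaurus_flags,
        umls_lexicon=umls_lexicon,
        umls_flags=umls_flags,
    )


def _variant_multi(head_tokens, tail_tokens, choice1, choice2):
    """One multi-overlap variant: vesicle[,formation] and membrane[,fusion]."""
    g1 = ("vesicle",) if choice1 == "short" else ("vesicle", "formation")
    g2 = ("membrane",) if choice2 == "short" else ("membrane", "fusion")
    c1 = "GO:0031982" if choice1 == "short" else "GO:0006900"
    c2 = "GO:0016020" if choice2 == "short" else "GO:0061025"
    mid = g1 + ("and",) + g2
    tokens = head_tokens + mid + (",",) + tail_tokens + (".",)
    tags = ["O"] * len(tokens)
    i1 = len(head_tokens)
    tags[i1] = f"B-{c1}"
    for k in range(1, len(g1)):
        tags[i1 + k] = f"I-{c1}"
    i2 = i1 + len(g1) + 1
    tags[i2] = f"B-{c2}"
    for k in range(1, len(g2)):
        tags[i2 + k] = f"I-{c2}"
    tags[-1] = "EOS"
    return tokens, tuple(tags)
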