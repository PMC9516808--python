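"""Core domain types shared across the pipeline."""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

SENTENCE_END_MARKS = {".", "!", "?"}
EOS_TAG = "EOS"
O_TAG = "O"
SYNTHETIC_EOS_TOKEN = "<EOS>"

#: GO namespace long names -> short codes used in reports.
NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class ArticleDocument:
    """A full-text article; annotation offsets are 0-based indices into text."""

    article_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError(f"article {self.article_id!r} has empty text")


@dataclass(frozen=True)
class ConceptAnnotation:
    """An ontology concept attached to one or more character spans.

    Spans are half-open ``[start, end)`` intervals, sorted ascending and
    non-overlapping.  Two or more spans mark a discontinuous annotation.
    """

    spans: tuple[tuple[int, int], ...]
    spanned_text: str
    concept_id: str

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValidationError("annotation has no spans")
        prev_end = -1
        for start, end in self.spans:
            if start >= end:
                raise ValidationError(
                    f"annotation {self.concept_id}: bad span ({start}, {end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"annotation {self.concept_id}: spans overlap or are unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    @property
    def discontinuous(self) -> bool:
        return len(self.spans) >= 2

    def overlaps(self, other: "ConceptAnnotation") -> bool:
        """True when any span of self shares characters with any span of other."""
        return any(
            s1 < e2 and s2 < e1
            for s1, e1 in self.spans
            for s2, e2 in other.spans
        )


@dataclass(frozen=True)
class SentenceRecord:
    """A tokenized sentence with absolute character offsets into the article."""

    article_id: str
    sent_index: int
    tokens: tuple[tuple[str, int, int], ...]  # (surface, start, end)

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    @property
    def start(self) -> int:
        return self.tokens[0][1]

    @property
    def end(self) -> int:
        return self.tokens[-1][2]


def validate_iob(tags: Sequence[str]) -> None:
    """Check IOB well-formedness; raise ValidationError on violation."""
    prev = None
    for i, tag in enumerate(tags):
        if tag in (O_TAG, EOS_TAG):
            prev = None
            continue
        if tag.startswith("B-"):
            prev = tag[2:]
        elif tag.startswith("I-"):
            if prev != tag[2:]:
                raise ValidationError(
                    f"tag {tag!r} at position {i} not preceded by B-/I- of the "
                    "same concept"
                )
        else:
            raise ValidationError(f"unknown tag {tag!r} at position {i}")
    if EOS_TAG in tags[:-1]:
        raise ValidationError("EOS tag before the final position")


@dataclass(frozen=True)
class TaggedSentence:
    """Tokenized sentence with per-token IOB tags; the unit of training data."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]
    provenance: tuple[str, int, int] = ("", 0, 0)  # (article_id, sent_index, variant_index)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValidationError(
                f"{len(self.tokens)} tokens vs {len(self.tags)} tags"
            )
        validate_iob(self.tags)


class OntologyGraph:
    """Concept DAG over is_a edges with GO-style namespaces.

    Ancestor sets (used by the Jaccard similarity) include the concept itself,
    so identical concepts have similarity 1.
    """

    def __init__(
        self,
        concepts: Iterable[str],
        name: Mapping[str, str],
        parents: Mapping[str, Iterable[str]],
        namespace: Mapping[str, str],
    ) -> None:
        self.concepts = frozenset(concepts)
        self.name = dict(name)
        self.parents = {c: frozenset(parents.get(c, ())) for c in self.concepts}
        self.namespace = dict(namespace)
        for c, ps in self.parents.items():
            missing = ps - self.concepts
            if missing:
                raise ValidationError(
                    f"concept {c}: unknown parent(s) {sorted(missing)}"
                )
        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ValidationError(f"is_a cycle through {node}")
            state[node] = 0
            for p in self.parents[node]:
                visit(p, stack)
            state[node] = 1

        for c in self.concepts:
            visit(c, [])

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """Transitive is_a closure of concept_id, including itself."""
        cached = self._anc_cache.get(concept_id)
        if cached is not None:
            return cached
        if concept_id not in self.concepts:
            raise KeyError(concept_id)
        closure = {concept_id}
        for p in self.parents[concept_id]:
            closure |= self.ancestors(p)
        result = frozenset(closure)
        self._anc_cache[concept_id] = result
        return result

    def namespace_code(self, concept_id: str) -> str:
        """Short sub-ontology code: BP, CC, MF, or 'other'."""
        ns = self.namespace.get(concept_id, "")
        return NAMESPACE_CODES.get(ns, ns if ns in {"BP", "CC", "MF"} else "other")

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)


@lru_cache(maxsize=65536)
def normalize_surface(surface: str) -> str:
    """NFC-normalized, case-folded lookup key for lexicon matching."""
    return unicodedata.normalize("NFC", surface).casefold()


@dataclass
class LexiconTable:
    """Surface string -> binary category flags (BioThesaurus/UMLS stand-in)."""

    entries: dict[str, tuple[int, ...]] = field(default_factory=dict)
    categories: tuple[str, ...] = ()
    max_phrase_len: int = 5

    def __post_init__(self) -> None:
        n = len(self.categories)
        for surface, flags in self.entries.items():
            if len(flags) != n or any(f not in (0, 1) for f in flags):
                raise ValidationError(
                    f"lexicon entry {surface!r}: flags {flags} do not match "
                    f"{n} categories or are not 0/1"
                )

    def lookup(self, surface: str) -> tuple[int, ...]:
        """Flag vector for a surface string; all zeros when absent."""
        return self.entries.get(
            normalize_surface(surface), (0,) * len(self.categories)
        )

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def is_go_tag(tag: str) -> bool:
    """True for B-/I- concept tags (as opposed to O/EOS)."""
    return tag.startswith("B-") or tag.startswith("I-")


def concept_of(tag: str) -> str:
    """Concept id carried by a B-/I- tag."""
    return tag[2:]
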