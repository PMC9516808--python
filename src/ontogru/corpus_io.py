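"""Readers and writers for articles, span-annotation XML, OBO ontologies,
lexicon TSVs and the CoNLL-style preprocessed format."""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import obonet

from ontogru.datatypes import (
    ArticleDocument,
    ConceptAnnotation,
    LexiconTable,
    OntologyGraph,
    TaggedSentence,
    ValidationError,
    normalize_surface,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_article",
    "read_annotation_xml",
    "read_obo",
    "read_lexicon",
    "write_conll",
    "read_conll",
    "ArticleDocument",
    "ConceptAnnotation",
    "OntologyGraph",
    "LexiconTable",
]


def read_article(path: str | Path) -> ArticleDocument:
    """Read a UTF-8 article; the article id is the file stem.

    A leading byte-order mark is stripped so that annotation offsets count
    from the first real character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"article file not found: {path}")
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8-sig")
    except UnicodeDecodeError as exc:
        raise ValidationError(
            f"{path}: not valid UTF-8 at byte offset {exc.start}"
        ) from exc
    if not text:
        raise ValidationError(f"{path}: article is empty")
    return ArticleDocument(article_id=path.stem, text=text)


def read_annotation_xml(
    path: str | Path, doc: ArticleDocument
) -> list[ConceptAnnotation]:
    """Parse a span-annotation XML file into ConceptAnnotations.

    Accepts both the knowtator-style layout (``<annotation>`` carrying a
    ``<mention id=.../>`` resolved through ``<classMention>``) and a
    simplified dialect where the concept is a ``<class id=.../>`` child or a
    ``class`` attribute.  Multiple ``<span>`` elements under one annotation
    yield a discontinuous annotation.  When the recorded spanned text
    disagrees with the article slice, the slice is authoritative and a
    warning is logged.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValidationError(f"{path}: malformed XML: {exc}") from exc

    mention_class: dict[str, str] = {}
    for cm in root.iter("classMention"):
        mid = cm.get("id")
        mc = cm.find("mentionClass")
        if mid and mc is not None and mc.get("id"):
            mention_class[mid] = mc.get("id")

    annotations: list[ConceptAnnotation] = []
    for i, ann in enumerate(root.iter("annotation")):
        ann_id = ann.get("id", f"#{i}")
        concept = _annotation_concept(ann, mention_class)
        if concept is None:
            raise ValidationError(f"{path}: annotation {ann_id} has no concept id")
        spans = []
        for span in ann.findall("span"):
            start, end = int(span.get("start")), int(span.get("end"))
            if not (0 <= start < end <= len(doc.text)):
                raise ValidationError(
                    f"{path}: annotation {ann_id} span ({start}, {end}) outside "
                    f"article of length {len(doc.text)}"
                )
            spans.append((start, end))
        if not spans:
            raise ValidationError(f"{path}: annotation {ann_id} has no spans")
        spans.sort()
        slice_text = " ... ".join(doc.text[s:e] for s, e in spans)
        recorded = ann.findtext("spannedText")
        if recorded is not None and recorded != slice_text:
            log.warning(
                "%s: annotation %s spannedText %r != article slice %r; "
                "using the slice",
                path, ann_id, recorded, slice_text,
            )
        annotations.append(
            ConceptAnnotation(
                spans=tuple(spans), spanned_text=slice_text, concept_id=concept
            )
        )
    return annotations


def _annotation_concept(ann: ET.Element, mention_class: dict[str, str]) -> str | None:
    cls = ann.find("class")
    if cls is not None and cls.get("id"):
        return cls.get("id")
    if ann.get("class"):
        return ann.get("class")
    mention = ann.find("mention")
    if mention is not None and mention.get("id") in mention_class:
        return mention_class[mention.get("id")]
    return None


def read_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 ontology, keeping only is_a edges.

    Obsolete terms are dropped (obonet excludes them); cycles and parents
    without a [Term] stanza raise a validation error.
    """
    graph = obonet.read_obo(Path(path))
    concepts = set(graph.nodes)
    name = {}
    namespace = {}
    parents: dict[str, set[str]] = {c: set() for c in concepts}
    for node, data in graph.nodes(data=True):
        if not data:
            raise ValidationError(
                f"{path}: {node} referenced as a parent but never defined"
            )
        name[node] = data.get("name", node)
        namespace[node] = data.get("namespace", "")
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    subgraph = nx.DiGraph(
        (c, p) for c, ps in parents.items() for p in ps
    )
    if subgraph.number_of_edges() and not nx.is_directed_acyclic_graph(subgraph):
        raise ValidationError(f"{path}: is_a graph contains a cycle")
    return OntologyGraph(concepts, name, parents, namespace)


def read_lexicon(
    path: str | Path, categories: Sequence[str], max_phrase_len: int = 5
) -> LexiconTable:
    """Read a TSV lexicon: surface string + one 0/1 column per category.

    Surface strings are matched case-insensitively (NFC-normalized);
    duplicate rows are OR-combined.
    """
    entries: dict[str, list[int]] = {}
    n = len(categories)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n + 1:
                raise ValidationError(
                    f"{path}:{lineno}: expected {n + 1} columns, got {len(fields)}"
                )
            surface = normalize_surface(fields[0])
            try:
                flags = [int(f) for f in fields[1:]]
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer flag"
                ) from None
            if any(f not in (0, 1) for f in flags):
                raise ValidationError(f"{path}:{lineno}: flags must be 0 or 1")
            if surface in entries:
                entries[surface] = [a | b for a, b in zip(entries[surface], flags)]
            else:
                entries[surface] = flags
    return LexiconTable(
        entries={k: tuple(v) for k, v in entries.items()},
        categories=tuple(categories),
        max_phrase_len=max_phrase_len,
    )


def write_conll(sentences: Iterable[TaggedSentence], path: str | Path) -> int:
    """Write sentences as token TAB tag lines, blank line between sentences.

    Provenance is preserved in a ``# doc= sent= variant=`` comment so the
    write -> read round trip is the identity.
    """
    count = 0
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            art, idx, var = sent.provenance
            fh.write(f"# doc={art} sent={idx} variant={var}\n")
            for token, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{token}\t{tag}\n")
            fh.write("\n")
            count += 1
    return count


def read_conll(path: str | Path) -> list[TaggedSentence]:
    """Read the CoNLL-style format written by write_conll.

    Malformed lines and ill-formed IOB sequences raise a validation error
    naming the line number.
    """
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    tags: list[str] = []
    provenance: tuple[str, int, int] = ("", len(sentences), 0)

    def flush(lineno: int) -> None:
        nonlocal tokens, tags, provenance
        if tokens:
            try:
                sentences.append(
                    TaggedSentence(tuple(tokens), tuple(tags), provenance)
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: sentence ending at line {lineno}: {exc}"
                ) from exc
        tokens, tags = [], []
        provenance = ("", len(sentences), 0)

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# doc="):
                provenance = _parse_provenance(line, len(sentences))
                continue
            if not line:
                flush(lineno)
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'token<TAB>tag', got {line!r}"
                )
            tokens.append(fields[0])
            tags.append(fields[1])
        flush(lineno)
    return sentences


def read_conll_tags(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read (tokens, tags) per sentence without IOB validation.

    Prediction files may carry ill-formed IOB sequences (tags are decoded by
    raw per-token argmax); extra columns beyond token and tag are ignored.
    """
    out: list[tuple[list[str], list[str]]] = []
    tokens: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line:
                if tokens:
                    out.append((tokens, tags))
                tokens, tags = [], []
                continue
            fields = line.split("\t")
            tokens.append(fields[0])
            tags.append(fields[1] if len(fields) > 1 else "O")
    if tokens:
        out.append((tokens, tags))
    return out


def _parse_provenance(line: str, default_index: int) -> tuple[str, int, int]:
    fields = dict(
        part.split("=", 1) for part in line[2:].split() if "=" in part
    )
    return (
        fields.get("doc", ""),
        int(fields.get("sent", default_index)),
        int(fields.get("variant", 0)),
    )
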