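"""Deterministic sentence segmentation, tokenization and POS tagging.

Rule-based and fully pinned inside the package so that preprocessing is
byte-reproducible across machines.  The tokenizer follows the conventions of
treebank-style tokenizers for biomedical text: enclosing punctuation is split
off, hyphenated compounds ("Smith-Lemli-Opitz", "DNA-binding") stay single
tokens, and a slash starts a new token that keeps its slash ("v/p" -> "v",
"/p").
"""

from __future__ import annotations

import re

OPEN_PUNCT = set("([{“\"'")
CLOSE_PUNCT = set(")]}”\"'.,;:!?")
_SENT_END = re.compile(r"[.!?]+")

Token = tuple[str, int, int]  # (surface, start, end)


def segment_text(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans (half-open character offsets).

    A sentence ends at '.', '!' or '?' followed by whitespace and an
    uppercase letter, digit or opening bracket/quote; newlines always end a
    sentence (titles and headings in full-text articles carry no period).
    """
    spans: list[tuple[int, int]] = []
    for line_start, line_end in _lines(text):
        start = line_start
        i = line_start
        while i < line_end:
            m = _SENT_END.match(text, i)
            if m and m.end() < line_end:
                j = m.end()
                k = j
                while k < line_end and text[k].isspace():
                    k += 1
                if k > j and k < line_end and (
                    text[k].isupper() or text[k].isdigit() or text[k] in OPEN_PUNCT
                ):
                    spans.append((start, j))
                    start = k
                    i = k
                    continue
            i += 1
        if start < line_end:
            spans.append((start, line_end))
    return [_strip_span(text, s, e) for s, e in spans if text[s:e].strip()]


def _lines(text: str):
    start = 0
    for i, ch in enumerate(text):
        if ch == "\n":
            if i > start:
                yield start, i
            start = i + 1
    if start < len(text):
        yield start, len(text)


def _strip_span(text: str, start: int, end: int) -> tuple[int, int]:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return start, end


def tokenize_span(text: str, start: int, end: int) -> list[Token]:
    """Tokenize text[start:end] into (surface, abs_start, abs_end) tokens."""
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text[start:end]):
        chunk_start = start + m.start()
        tokens.extend(_split_chunk(m.group(), chunk_start))
    return tokens


def _split_chunk(chunk: str, offset: int) -> list[Token]:
    lead: list[Token] = []
    trail: list[Token] = []
    s, e = 0, len(chunk)
    while s < e and chunk[s] in OPEN_PUNCT:
        lead.append((chunk[s], offset + s, offset + s + 1))
        s += 1
    while e > s and chunk[e - 1] in CLOSE_PUNCT:
        trail.append((chunk[e - 1], offset + e - 1, offset + e))
        e -= 1
    core = chunk[s:e]
    mids: list[Token] = []
    if core:
        # a slash starts a new token and stays attached to what follows
        pos = s
        for part in re.split(r"(?=/)", core):
            if part:
                mids.append((part, offset + pos, offset + pos + len(part)))
                pos += len(part)
    return lead + mids + list(reversed(trail))


def tokenize_sentences(text: str) -> list[list[Token]]:
    """Segment and tokenize; returns one token list per sentence."""
    return [tokenize_span(text, s, e) for s, e in segment_text(text)]


# ---------------------------------------------------------------------------
# POS tagging: a compact Penn-treebank-style rule tagger.
# ---------------------------------------------------------------------------

_PUNCT_TAGS = {
    "(": "-LRB-", ")": "-RRB-", "[": "-LRB-", "]": "-RRB-",
    "{": "-LRB-", "}": "-RRB-",
    ",": ",", ".": ".", "!": ".", "?": ".", ";": ":", ":": ":",
    "“": "``", "”": "''", '"': "''", "'": "''",
}

_WORD_TAGS = {
    "a": "DT", "an": "DT", "the": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "some": "DT", "all": "DT",
    "no": "DT", "any": "DT",
    "in": "IN", "of": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "to": "TO", "during": "IN", "between": "IN",
    "within": "IN", "into": "IN", "under": "IN", "over": "IN",
    "through": "IN", "as": "IN", "because": "IN", "if": "IN", "while": "IN",
    "after": "IN", "before": "IN", "via": "IN", "than": "IN", "due": "JJ",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "will": "MD",
    "would": "MD", "should": "MD", "must": "MD", "shall": "MD",
    "we": "PRP", "it": "PRP", "they": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "you": "PRP",
    "our": "PRP$", "its": "PRP$", "their": "PRP$", "his": "PRP$",
    "her": "PRP$", "my": "PRP$", "your": "PRP$",
    "which": "WDT", "who": "WP", "whose": "WP$", "what": "WP", "when": "WRB",
    "where": "WRB", "how": "WRB", "why": "WRB",
    "not": "RB", "also": "RB", "most": "RBS", "more": "RBR", "very": "RB",
    "there": "EX",
}

_NUM_RE = re.compile(r"^[\d][\d.,/+\-]*$|^[\d]+$")


def pos_tag(tokens: list[str]) -> list[str]:
    """Assign one Penn-style POS tag per token.

    Deterministic closed-class lexicon + suffix/shape rules; adequate for the
    15-20 tag granularity used as a model input channel.
    """
    tags: list[str] = []
    for i, tok in enumerate(tokens):
        tags.append(_tag_one(tok, first=(i == 0)))
    return tags


def _tag_one(tok: str, first: bool) -> str:
    if tok in _PUNCT_TAGS:
        return _PUNCT_TAGS[tok]
    if all(not ch.isalnum() for ch in tok):
        return "SYM"
    low = tok.lower()
    if low in _WORD_TAGS and (first or not tok[0].isupper()):
        return _WORD_TAGS[low]
    if _NUM_RE.match(tok):
        return "CD"
    if any(ch.isupper() for ch in tok):
        return "NNP"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBN"
    if low.endswith("es") and len(low) > 4 and low.endswith(("zes", "ses", "xes")):
        return "VBZ"
    if low.endswith("s") and len(low) > 3 and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"
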