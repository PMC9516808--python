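"""Vocabularies and the six fixed-shape per-sentence input channels.

Each sentence becomes: token ids, a token x character id matrix, compressed
character-representation ids, POS ids, four BioThesaurus category flags and
one UMLS presence flag, all padded/truncated to a fixed number of tokens
(default 71) and characters per token (default 15).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ontogru import tokenization
from ontogru.datatypes import LexiconTable, TaggedSentence, normalize_surface

__all__ = [
    "EncoderConfig",
    "Vocabulary",
    "EncodedSentence",
    "encode_char_repr",
    "pos_tag",
    "biothesaurus_encode",
    "umls_encode",
    "build_vocabularies",
    "encode_sentence",
    "encode_corpus",
]

PAD = "<PAD>"
UNK = "<UNK>"

BIOTHESAURUS_CATEGORIES = ("protein", "biomedical", "chemical", "macromolecule")

_PUNCT = set(string.punctuation)


@dataclass(frozen=True)
class EncoderConfig:
    """Fixed input geometry.

    The token and character limits follow the third standard deviation of
    the corresponding length distributions in the corpus this architecture
    was designed for: at most 71 tokens per sentence and 15 characters per
    token.
    """

    max_tokens: int = 71
    max_chars: int = 15
    pad_token: str = PAD
    unk_token: str = UNK
    umls_max_phrase_len: int = 5

    def __post_init__(self) -> None:
        if self.max_tokens < 1 or self.max_chars < 1:
            raise ValueError("max_tokens and max_chars must be >= 1")
        if self.pad_token == self.unk_token:
            raise ValueError("pad and unk tokens must differ")


class Vocabulary:
    """Dense bijective symbol <-> id map with reserved pad (0) and unk (1)."""

    def __init__(self, symbols: Iterable[str], pad: str = PAD, unk: str = UNK):
        self.pad, self.unk = pad, unk
        self._sym_to_id: dict[str, int] = {pad: 0, unk: 1}
        for sym in symbols:
            if sym not in self._sym_to_id:
                self._sym_to_id[sym] = len(self._sym_to_id)
        self._id_to_sym = {i: s for s, i in self._sym_to_id.items()}

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    def encode(self, symbol: str) -> int:
        return self._sym_to_id.get(symbol, 1)

    def decode(self, idx: int) -> str:
        return self._id_to_sym[idx]

    def __len__(self) -> int:
        return len(self._sym_to_id)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._sym_to_id

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self._sym_to_id, ensure_ascii=False, indent=0)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        mapping = json.loads(Path(path).read_text())
        vocab = cls.__new__(cls)
        vocab._sym_to_id = mapping
        vocab._id_to_sym = {i: s for s, i in mapping.items()}
        inverse = [s for s, _ in sorted(mapping.items(), key=lambda kv: kv[1])]
        vocab.pad, vocab.unk = inverse[0], inverse[1]
        return vocab


@dataclass
class EncodedSentence:
    """The six fixed-shape input channels plus labels and mask."""

    token_ids: np.ndarray  # (max_tokens,)
    char_ids: np.ndarray  # (max_tokens, max_chars)
    repr_ids: np.ndarray  # (max_tokens,)
    pos_ids: np.ndarray  # (max_tokens,)
    biot_flags: np.ndarray  # (max_tokens, 4)
    umls_flags: np.ndarray  # (max_tokens,)
    tag_ids: np.ndarray  # (max_tokens,)
    mask: np.ndarray  # (max_tokens,), 1 = real token
    tokens: tuple[str, ...] = ()  # surfaces actually encoded (post-truncation)
    tags: tuple[str, ...] = ()
    provenance: tuple[str, int, int] = ("", 0, 0)


def encode_char_repr(token: str) -> str:
    """Compress a token into a character-class pattern.

    Each maximal alphabetic run is reduced to the case classes ('C'/'c') of
    its first three characters, each digit run becomes a single 'N',
    punctuation is kept verbatim, and anything else becomes 'U'.  Examples:
    "Smith-Lemli-Opitz" -> "Ccc-Ccc-Ccc", "DHCR7" -> "CCCN", "2-5" -> "N-N".
    """
    out: list[str] = []
    i = 0
    n = len(token)
    while i < n:
        ch = token[i]
        if ch.isalpha():
            j = i
            while j < n and token[j].isalpha():
                j += 1
            out.append(
                "".join("C" if c.isupper() else "c" for c in token[i : i + 3])
                if j - i >= 3
                else "".join("C" if c.isupper() else "c" for c in token[i:j])
            )
            i = j
        elif ch.isdigit():
            while i < n and token[i].isdigit():
                i += 1
            out.append("N")
        elif ch in _PUNCT:
            out.append(ch)
            i += 1
        else:
            out.append("U")
            i += 1
    return "".join(out)


def pos_tag(tokens: Sequence[str]) -> list[str]:
    """POS tags from the package's pinned rule-based Penn-style tagger."""
    return tokenization.pos_tag(list(tokens))


def biothesaurus_encode(
    tokens: Sequence[str], lexicon: LexiconTable
) -> np.ndarray:
    """Per-token protein/biomedical/chemical/macromolecule flags.

    A token absent from the lexicon gets all zeros; several categories may
    be set at once.  Returns shape (len(tokens), n_categories).
    """
    return np.array([lexicon.lookup(tok) for tok in tokens], dtype=np.int64).reshape(
        len(tokens), len(lexicon.categories)
    )


def umls_encode(tokens: Sequence[str], lexicon: LexiconTable) -> np.ndarray:
    """Per-token UMLS presence flags with phrase lookup.

    Any n-gram (n up to lexicon.max_phrase_len) found in the lexicon marks
    all of its member tokens as present.
    """
    flags = np.zeros(len(tokens), dtype=np.int64)
    max_n = max(1, lexicon.max_phrase_len)
    for n in range(1, max_n + 1):
        for i in range(len(tokens) - n + 1):
            phrase = " ".join(normalize_surface(t) for t in tokens[i : i + n])
            if phrase in lexicon.entries:
                flags[i : i + n] = 1
    return flags


def build_vocabularies(
    train_sentences: Sequence[TaggedSentence],
) -> dict[str, Vocabulary]:
    """Build the five vocabularies (token/char/repr/pos/tag) from training
    data only; unseen test symbols map to the unk id at encode time."""
    if not train_sentences:
        raise ValueError("cannot build vocabularies from an empty training set")
    tokens: list[str] = []
    chars: list[str] = []
    reprs: list[str] = []
    pos: list[str] = []
    tags: list[str] = ["O", "EOS"]
    for sent in train_sentences:
        tokens.extend(sent.tokens)
        for tok in sent.tokens:
            chars.extend(tok)
            reprs.append(encode_char_repr(tok))
        pos.extend(pos_tag(sent.tokens))
        tags.extend(sent.tags)
    return {
        "token": Vocabulary(sorted(set(tokens))),
        "char": Vocabulary(sorted(set(chars))),
        "repr": Vocabulary(sorted(set(reprs))),
        "pos": Vocabulary(sorted(set(pos))),
        "tag": Vocabulary(["O", "EOS"] + sorted(set(tags) - {"O", "EOS"})),
    }


def encode_sentence(
    tagged: TaggedSentence,
    vocabularies: Mapping[str, Vocabulary],
    lexicons: Mapping[str, LexiconTable] | None,
    config: EncoderConfig = EncoderConfig(),
) -> EncodedSentence:
    """Produce all six channels for one sentence.

    Truncation keeps the left prefix (tokens 1..max_tokens, characters
    1..max_chars); shorter sentences are padded on the right and masked out.
    """
    lexicons = lexicons or {}
    T, C = config.max_tokens, config.max_chars
    tokens = list(tagged.tokens)[:T]
    tags = list(tagged.tags)[:T]
    n = len(tokens)

    token_ids = np.zeros(T, dtype=np.int64)
    char_ids = np.zeros((T, C), dtype=np.int64)
    repr_ids = np.zeros(T, dtype=np.int64)
    pos_ids = np.zeros(T, dtype=np.int64)
    biot = np.zeros((T, len(BIOTHESAURUS_CATEGORIES)), dtype=np.int64)
    umls = np.zeros(T, dtype=np.int64)
    tag_ids = np.zeros(T, dtype=np.int64)
    mask = np.zeros(T, dtype=np.int64)

    tok_vocab = vocabularies["token"]
    char_vocab = vocabularies["char"]
    repr_vocab = vocabularies["repr"]
    pos_vocab = vocabularies["pos"]
    tag_vocab = vocabularies["tag"]

    pos_tags = pos_tag(tokens)
    for i, tok in enumerate(tokens):
        token_ids[i] = tok_vocab.encode(tok)
        for j, ch in enumerate(tok[:C]):
            char_ids[i, j] = char_vocab.encode(ch)
        repr_ids[i] = repr_vocab.encode(encode_char_repr(tok))
        pos_ids[i] = pos_vocab.encode(pos_tags[i])
        tag_ids[i] = tag_vocab.encode(tags[i])
        mask[i] = 1
    if "biothesaurus" in lexicons and n:
        biot[:n] = biothesaurus_encode(tokens, lexicons["biothesaurus"])
    if "umls" in lexicons and n:
        umls[:n] = umls_encode(tokens, lexicons["umls"])

    return EncodedSentence(
        token_ids=token_ids,
        char_ids=char_ids,
        repr_ids=repr_ids,
        pos_ids=pos_ids,
        biot_flags=biot,
        umls_flags=umls,
        tag_ids=tag_ids,
        mask=mask,
        tokens=tuple(tokens),
        tags=tuple(tags),
        provenance=tagged.provenance,
    )


def encode_corpus(
    sentences: Sequence[TaggedSentence],
    vocabularies: Mapping[str, Vocabulary],
    lexicons: Mapping[str, LexiconTable] | None,
    config: EncoderConfig = EncoderConfig(),
) -> list[EncodedSentence]:
    return [encode_sentence(s, vocabularies, lexicons, config) for s in sentences]
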