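"""Model serialization and top-k query suggestion by cosine similarity.

The persisted model is a binary associative list of word -> vector records:

    magic "QSM1" | uint32 version | uint32 |V| | uint32 dim
    then |V| records of (uint16 UTF-8 byte length, term bytes, dim float32)

all integers little-endian. Suggestions are an exact full scan: cosine
similarity between the query vector and every vocabulary vector, the
query's own tokens excluded, ties broken lexicographically.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import PHRASE_DELIMITER, Tokenizer, merge_phrases, tokenize
from .train import EmbeddingModel

__all__ = [
    "ModelFormatError",
    "OutOfVocabularyError",
    "SuggestionList",
    "save_model",
    "load_model",
    "query_vector",
    "top_k",
]

MAGIC = b"QSM1"
FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised on a corrupt or truncated model file; names the byte offset."""


class OutOfVocabularyError(KeyError):
    """Raised when no token of a query is in the model vocabulary."""


@dataclass(frozen=True)
class SuggestionList:
    """Ranked alternative query terms with cosine scores (non-increasing)."""

    entries: tuple[tuple[str, float], ...]

    def terms(self) -> list[str]:
        return [t for t, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Write the word vectors as the QSM1 binary associative list.

    Inner-node vectors are training state and are not persisted. Vectors
    are stored as float32; a float32 model round-trips bit-exactly.
    """
    if len(model) == 0:
        raise ValueError("refusing to save a model with an empty vocabulary")
    with Path(path).open("wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<III", FORMAT_VERSION, len(model), model.dim))
        for word, row in zip(model.words, model.matrix):
            raw = word.encode("utf-8")
            if len(raw) > 0xFFFF:
                raise ValueError(f"term too long to serialize: {word[:40]}…")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
            fh.write(np.asarray(row, dtype="<f4").tobytes())


def load_model(path: str | Path) -> EmbeddingModel:
    """Read a QSM1 model file; raises ModelFormatError naming the byte
    offset of the first inconsistency."""
    data = Path(path).read_bytes()
    if data[:4] != MAGIC:
        raise ModelFormatError(f"bad magic bytes at offset 0: {data[:4]!r}")
    if len(data) < 16:
        raise ModelFormatError(f"truncated header at offset {len(data)}")
    version, n_words, dim = struct.unpack_from("<III", data, 4)
    if version != FORMAT_VERSION:
        raise ModelFormatError(f"unsupported format version {version} at offset 4")
    offset = 16
    words: list[str] = []
    matrix = np.empty((n_words, dim), dtype=np.float32)
    vec_bytes = 4 * dim
    for i in range(n_words):
        if offset + 2 > len(data):
            raise ModelFormatError(
                f"truncated record {i}: expected term length at offset {offset}"
            )
        (term_len,) = struct.unpack_from("<H", data, offset)
        offset += 2
        end = offset + term_len + vec_bytes
        if end > len(data):
            raise ModelFormatError(
                f"truncated record {i}: payload ends at offset {len(data)}, "
                f"expected {end}"
            )
        words.append(data[offset : offset + term_len].decode("utf-8"))
        matrix[i] = np.frombuffer(
            data, dtype="<f4", count=dim, offset=offset + term_len
        )
        offset += term_len + vec_bytes
    if offset != len(data):
        raise ModelFormatError(
            f"{len(data) - offset} trailing bytes at offset {offset}"
        )
    return EmbeddingModel(words, matrix)


def _model_phrases(model: EmbeddingModel) -> set[tuple[str, str]]:
    """Phrase pairs implied by underscore-joined vocabulary entries."""
    phrases = set()
    for word in model.words:
        if PHRASE_DELIMITER in word:
            a, _, b = word.partition(PHRASE_DELIMITER)
            if a and b:
                phrases.add((a, b))
    return phrases


def _query_tokens(
    model: EmbeddingModel, query: str, tokenizer: Tokenizer | None = None
) -> list[str]:
    tok = tokenizer(query) if tokenizer else tokenize(query)
    return merge_phrases(tok, _model_phrases(model))


def query_vector(
    model: EmbeddingModel, query: str, tokenizer: Tokenizer | None = None
) -> np.ndarray:
    """Vector for a (possibly multi-word) query.

    The query is tokenized and phrase-merged against the model's phrase
    inventory; if the fully joined phrase token is in the vocabulary its
    vector is returned, otherwise the mean of the in-vocabulary token
    vectors. Raises OutOfVocabularyError if no token is known.
    """
    raw = tokenizer(query) if tokenizer else tokenize(query)
    if not raw:
        raise OutOfVocabularyError(f"query has no tokens: {query!r}")
    joined = PHRASE_DELIMITER.join(raw)
    if joined in model:
        return model.vector(joined)
    tokens = merge_phrases(raw, _model_phrases(model))
    known = [t for t in tokens if t in model]
    if not known:
        raise OutOfVocabularyError(f"no query token in vocabulary: {query!r}")
    return model.matrix[[model.index(t) for t in known]].mean(axis=0)


def top_k(
    model: EmbeddingModel,
    query: str,
    k: int = 5,
    tokenizer: Tokenizer | None = None,
) -> SuggestionList:
    """Exact top-k vocabulary words by cosine similarity to the query.

    Excluded from candidacy: the query's own tokens (raw and phrase-merged),
    the fully joined phrase, and zero-norm vectors (cosine undefined).
    Ties are broken lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qv = np.asarray(query_vector(model, query, tokenizer), dtype=np.float64)
    qnorm = float(np.linalg.norm(qv))
    if qnorm == 0.0:
        raise OutOfVocabularyError(
            f"query vector has zero norm, cosine undefined: {query!r}"
        )
    raw = tokenizer(query) if tokenizer else tokenize(query)
    excluded = set(raw)
    excluded.update(_query_tokens(model, query, tokenizer))
    excluded.add(PHRASE_DELIMITER.join(raw))

    matrix = np.asarray(model.matrix, dtype=np.float64)
    norms = np.linalg.norm(matrix, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (matrix @ qv) / (norms * qnorm)
    candidates = [
        (word, float(scores[i]))
        for i, word in enumerate(model.words)
        if norms[i] > 0.0 and word not in excluded
    ]
    candidates.sort(key=lambda ws: (-ws[1], ws[0]))
    return SuggestionList(entries=tuple(candidates[:k]))
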