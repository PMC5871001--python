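"""Corpus preprocessing: tokenization, n-gram counting and collocation phrase mining.

The phrase miner follows the discounted collocation score

    score(w_i, w_j) = (count(w_i w_j) - delta) / (count(w_i) * count(w_j))

where ``delta`` discounts phrases built from very infrequent words. Ordered
word pairs whose score exceeds a threshold are merged into single phrase
tokens (``salt stress`` -> ``salt_stress``) so that downstream vector
training treats them as one vocabulary entry. The threshold can be
calibrated by measuring the overlap of mined phrases with ontology term
labels.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Document",
    "CorpusStats",
    "PhraseConfig",
    "Tokenizer",
    "tokenize",
    "count_ngrams",
    "phrase_score",
    "extract_phrases",
    "merge_phrases",
    "ontology_overlap",
    "read_corpus",
    "write_corpus",
]

#: Database-identifier pattern: letters immediately followed by digits,
#: optionally interleaved, with dotted/hyphenated suffixes (gene loci such
#: as ``at1g01010``, accessions such as ``q9s7u2-2``). Kept as one token so
#: identifiers are never split apart.
DEFAULT_IDENTIFIER_PATTERN = r"[^\W\d_]+\d[^\W_]*(?:[.\-][^\W_]+)*"

#: A plain word: unicode letters/digits, underscore excluded (the underscore
#: is reserved as the phrase join delimiter).
_WORD_PATTERN = r"[^\W_]+"

PHRASE_DELIMITER = "_"


@dataclass(frozen=True)
class Document:
    """A single text record (e.g. one abstract or one function description)."""

    doc_id: str
    text: str


@dataclass
class CorpusStats:
    """Unigram and ordered adjacent-bigram counts for a tokenized corpus."""

    unigram_counts: Counter = field(default_factory=Counter)
    bigram_counts: Counter = field(default_factory=Counter)
    total_tokens: int = 0

    def update(self, tokens: Sequence[str]) -> None:
        self.unigram_counts.update(tokens)
        self.bigram_counts.update(zip(tokens, tokens[1:]))
        self.total_tokens += len(tokens)


@dataclass(frozen=True)
class PhraseConfig:
    """Parameters of the collocation score filter.

    delta: discounting coefficient; pairs occurring <= delta times score <= 0.
    score_threshold: minimum (exclusive) score for a pair to become a phrase.
    max_phrase_passes: number of merge passes; >1 lets already-joined phrase
        tokens pair up again, yielding longer phrases.
    """

    delta: float = 5.0
    score_threshold: float = 9e-8
    max_phrase_passes: int = 1

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be non-negative")
        if self.max_phrase_passes < 1:
            raise ValueError("max_phrase_passes must be >= 1")


class Tokenizer:
    """Unicode tokenizer that lowercases and preserves database identifiers.

    Tokens are maximal runs of unicode word characters (underscore excluded);
    substrings matching ``identifier_pattern`` are emitted unsplit, so
    ``AT1G01010`` or ``q9s7u2-2`` survive as single tokens while ordinary
    hyphenated words are split at the hyphen.
    """

    def __init__(self, identifier_pattern: str = DEFAULT_IDENTIFIER_PATTERN):
        self._regex = re.compile(
            f"(?:{identifier_pattern})|(?:{_WORD_PATTERN})", re.UNICODE
        )

    def __call__(self, text: str) -> list[str]:
        return self._regex.findall(text.lower())


_DEFAULT_TOKENIZER = Tokenizer()


def tokenize(text: str) -> list[str]:
    """Tokenize with the default identifier-preserving tokenizer."""
    return _DEFAULT_TOKENIZER(text)


def count_ngrams(
    documents: Iterable[Document], tokenizer: Tokenizer | None = None
) -> CorpusStats:
    """Count unigrams and adjacent ordered bigrams, per document.

    Bigrams never span document boundaries.
    """
    tok = tokenizer or _DEFAULT_TOKENIZER
    stats = CorpusStats()
    for doc in documents:
        stats.update(tok(doc.text))
    return stats


def phrase_score(
    count_ij: float, count_i: float, count_j: float, delta: float = 5.0
) -> float:
    """Discounted collocation score (count_ij - delta) / (count_i * count_j)."""
    denom = count_i * count_j
    if denom == 0:
        raise ZeroDivisionError(
            "phrase_score requires positive unigram counts for both words"
        )
    return (count_ij - delta) / denom


def extract_phrases(
    stats: CorpusStats, config: PhraseConfig = PhraseConfig()
) -> set[tuple[str, str]]:
    """Return every ordered pair whose collocation score exceeds the threshold."""
    phrases: set[tuple[str, str]] = set()
    for (wi, wj), cij in stats.bigram_counts.items():
        score = phrase_score(
            cij, stats.unigram_counts[wi], stats.unigram_counts[wj], config.delta
        )
        if score > config.score_threshold:
            phrases.add((wi, wj))
    return phrases


def merge_phrases(
    tokens: Sequence[str], phrases: set[tuple[str, str]]
) -> list[str]:
    """Greedy left-to-right, non-overlapping replacement of phrase pairs.

    A matched pair is replaced by a single underscore-joined token; the
    leftmost candidate wins when candidates overlap.
    """
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and (tokens[i], tokens[i + 1]) in phrases:
            out.append(tokens[i] + PHRASE_DELIMITER + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def ontology_overlap(
    phrases: set[tuple[str, str]], term_labels: Iterable[str]
) -> tuple[int, float]:
    """Count mined phrases whose space-joined form matches an ontology label.

    ``term_labels`` should be normalized with the same tokenizer (see
    :func:`normalize_label`); matching is case-insensitive and exact.
    Returns (count, fraction of phrases matched).
    """
    labels = {label.lower() for label in term_labels}
    hits = sum(1 for wi, wj in phrases if f"{wi} {wj}" in labels)
    fraction = hits / len(phrases) if phrases else 0.0
    return hits, fraction


def normalize_label(label: str, tokenizer: Tokenizer | None = None) -> str:
    """Normalize an ontology label the same way corpus text is tokenized."""
    tok = tokenizer or _DEFAULT_TOKENIZER
    return " ".join(tok(label))


def read_corpus(path: str | Path) -> Iterator[Document]:
    """Read documents from a UTF-8 file (one document per line) or a
    directory of ``.txt`` files (one document per file)."""
    path = Path(path)
    if path.is_dir():
        for txt in sorted(path.glob("*.txt")):
            yield Document(doc_id=txt.stem, text=txt.read_text(encoding="utf-8"))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                yield Document(doc_id=str(lineno), text=line.rstrip("\n"))


def write_corpus(
    documents: Iterable[Sequence[str]], path: str | Path
) -> None:
    """Write tokenized documents one per line, tokens space-separated."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for tokens in documents:
            fh.write(" ".join(tokens) + "\n")


def rewrite_corpus(
    documents: Iterable[Document],
    phrases: set[tuple[str, str]],
    tokenizer: Tokenizer | None = None,
    passes: int = 1,
) -> list[list[str]]:
    """Tokenize and phrase-merge every document (``passes`` merge passes)."""
    tok = tokenizer or _DEFAULT_TOKENIZER
    out = []
    for doc in documents:
        tokens = tok(doc.text)
        for _ in range(passes):
            tokens = merge_phrases(tokens, phrases)
        out.append(tokens)
    return out
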