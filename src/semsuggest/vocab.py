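"""Frequency-filtered vocabulary and the Huffman tree for hierarchical softmax.

The hierarchical softmax output layer factorizes P(word | context) over a
binary tree whose leaves are vocabulary words. Building that tree with the
Huffman algorithm on word frequencies gives frequent words short root-leaf
paths, so the expected cost of a probability evaluation is O(log2 |V|).
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Vocabulary", "HuffmanTree", "build_vocabulary", "build_huffman"]


@dataclass(frozen=True)
class Vocabulary:
    """Word -> (index, frequency) map with deterministic indexing.

    Indices run 0..|V|-1 in order of descending frequency, ties broken
    lexicographically.
    """

    words: tuple[str, ...]
    frequencies: tuple[int, ...]
    total_count: int

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {w: i for i, w in enumerate(self.words)}
        )

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    def frequency(self, word: str) -> int:
        return self.frequencies[self._index[word]]

    def to_tsv(self) -> str:
        lines = [
            f"{w}\t{i}\t{f}"
            for i, (w, f) in enumerate(zip(self.words, self.frequencies))
        ]
        return "\n".join(lines) + "\n"


def build_vocabulary(
    corpus: Iterable[Sequence[str]] | Iterable[str], min_count: int = 5
) -> Vocabulary:
    """Count tokens and keep those with frequency >= min_count.

    ``corpus`` is either a flat token stream or an iterable of token lists.
    Raises ValueError if nothing survives the filter.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter = Counter()
    for item in corpus:
        if isinstance(item, str):
            counts[item] += 1
        else:
            counts.update(item)
    kept = [(w, c) for w, c in counts.items() if c >= min_count]
    if not kept:
        raise ValueError(
            f"empty vocabulary: no token reached min_count={min_count}"
        )
    kept.sort(key=lambda wc: (-wc[1], wc[0]))
    words, freqs = zip(*kept)
    return Vocabulary(words=words, frequencies=freqs, total_count=sum(freqs))


class HuffmanTree:
    """Per-word binary codes and inner-node paths of a Huffman tree.

    For word w, ``code(w)`` is its bit sequence from the root and
    ``path(w)`` the inner-node indices visited, aligned with the code
    (path[k] is the node where bit code[k] is taken). A vocabulary of n >= 2
    words yields exactly n - 1 inner nodes; a single-word vocabulary
    degenerates to an empty code (the word has probability one).
    """

    def __init__(
        self,
        codes: dict[str, tuple[int, ...]],
        paths: dict[str, tuple[int, ...]],
        inner_node_count: int,
    ):
        self._codes = codes
        self._paths = paths
        self.inner_node_count = inner_node_count
        # int32 arrays for the training inner loop
        self._code_arrays = {
            w: np.asarray(c, dtype=np.int8) for w, c in codes.items()
        }
        self._path_arrays = {
            w: np.asarray(p, dtype=np.int32) for w, p in paths.items()
        }
        # sign s_k = +1 for bit 0, -1 for bit 1
        self._sign_arrays = {
            w: (1.0 - 2.0 * c).astype(np.float64)
            for w, c in self._code_arrays.items()
        }

    def code(self, word: str) -> tuple[int, ...]:
        return self._codes[word]

    def path(self, word: str) -> tuple[int, ...]:
        return self._paths[word]

    def signs(self, word: str) -> np.ndarray:
        return self._sign_arrays[word]

    def path_array(self, word: str) -> np.ndarray:
        return self._path_arrays[word]

    def words(self):
        return self._codes.keys()


def build_huffman(vocab: Vocabulary) -> HuffmanTree:
    """Classic Huffman construction over vocabulary frequencies.

    Deterministic tie rule: among equal weights the earliest-inserted node
    is merged first; bit 0 goes to the lower-weight (then earlier-inserted)
    child. Leaves are inserted in vocabulary index order.
    """
    n = len(vocab)
    if n == 0:
        raise ValueError("cannot build a Huffman tree over an empty vocabulary")
    if n == 1:
        return HuffmanTree({vocab.words[0]: ()}, {vocab.words[0]: ()}, 0)

    # heap entries: (weight, insertion_order, node_key)
    # node_key: ("leaf", word_index) or ("inner", inner_index)
    heap: list[tuple[int, int, tuple[str, int]]] = []
    order = 0
    for i, freq in enumerate(vocab.frequencies):
        heapq.heappush(heap, (freq, order, ("leaf", i)))
        order += 1

    children: dict[int, tuple[tuple[str, int], tuple[str, int]]] = {}
    inner_index = 0
    while len(heap) > 1:
        w0, _, left = heapq.heappop(heap)   # bit 0: lower weight / earlier
        w1, _, right = heapq.heappop(heap)  # bit 1
        children[inner_index] = (left, right)
        heapq.heappush(heap, (w0 + w1, order, ("inner", inner_index)))
        order += 1
        inner_index += 1

    root = heap[0][2]
    codes: dict[str, tuple[int, ...]] = {}
    paths: dict[str, tuple[int, ...]] = {}
    # iterative DFS from the root, accumulating (code, path)
    stack = [(root, (), ())]
    while stack:
        node, code, path = stack.pop()
        kind, idx = node
        if kind == "leaf":
            codes[vocab.words[idx]] = code
            paths[vocab.words[idx]] = path
        else:
            left, right = children[idx]
            stack.append((left, code + (0,), path + (idx,)))
            stack.append((right, code + (1,), path + (idx,)))

    return HuffmanTree(codes, paths, inner_index)
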