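"""Word-vector training: CBOW and Skip-gram with hierarchical softmax.

Both architectures learn from (context, target) pairs drawn from a sliding
window. CBOW predicts the center word from the mean of its context-word
vectors; Skip-gram predicts each window word from the center word's vector.
The output layer is a hierarchical softmax over a Huffman tree: the
probability of a target word is the product of logistic decisions along its
root-leaf path,

    P(w | c) = prod_k sigmoid(s_k * <v_{n_k}, c>),   s_k = +1 if bit_k == 0 else -1,

which costs len(code(w)) = O(log2 |V|) dot products per evaluation.
Optimization is plain SGD with a linearly decaying learning rate; training
is single-threaded and bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .vocab import HuffmanTree, Vocabulary

__all__ = [
    "TrainingConfig",
    "EmbeddingModel",
    "hs_probability",
    "hs_gradient_step",
    "train",
    "skipgram_pairs",
    "cbow_contexts",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of a training run.

    architecture: "cbow" or "skipgram".
    dim: word-vector dimensionality (200 matches the production setting).
    window: context words taken on each side of the center word.
    epochs: full passes over the corpus.
    initial_lr / min_lr: the learning rate decays linearly from the former
        to the latter over all training tokens.
    subsample_threshold: frequent-word subsampling threshold t; a token with
        corpus frequency fraction f is kept with probability
        (sqrt(f/t) + 1) * t / f. 0 disables subsampling.
    """

    architecture: str = "skipgram"
    dim: int = 200
    window: int = 5
    epochs: int = 5
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    seed: int = 1
    subsample_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.architecture not in ("cbow", "skipgram"):
            raise ValueError("architecture must be 'cbow' or 'skipgram'")
        if self.dim < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("dim, window and epochs must be positive")
        if not 0 < self.initial_lr or not 0 <= self.min_lr <= self.initial_lr:
            raise ValueError("need 0 <= min_lr <= initial_lr and initial_lr > 0")


class EmbeddingModel:
    """Dense word vectors plus the inner-node vectors used during training.

    ``matrix`` holds one row per vocabulary word (input vectors); ``inner``
    holds one row per Huffman inner node and exists only for training /
    probability evaluation — suggestion queries use the word vectors alone.
    """

    def __init__(
        self,
        words: Sequence[str],
        matrix: np.ndarray,
        inner: np.ndarray | None = None,
    ):
        if matrix.ndim != 2 or len(words) != matrix.shape[0]:
            raise ValueError("matrix must have one row per word")
        self.words = list(words)
        self.matrix = matrix
        self.inner = inner
        self.dim = matrix.shape[1]
        self._index = {w: i for i, w in enumerate(self.words)}
        self.epoch_losses: list[float] = []

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._index[word]]
        except KeyError:
            raise KeyError(f"word not in model vocabulary: {word!r}") from None


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # numerically stable logistic
    return np.where(
        x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 50))),
        np.exp(np.clip(x, -50, None)) / (1.0 + np.exp(np.clip(x, -50, None))),
    )


def hs_probability(
    model: EmbeddingModel,
    tree: HuffmanTree,
    target: str,
    context_vector: np.ndarray,
) -> float:
    """P(target | context) under the hierarchical softmax.

    Evaluates exactly len(code(target)) inner-node terms; the probabilities
    over the whole vocabulary sum to one for any context vector.
    """
    if model.inner is None:
        raise ValueError("model carries no inner-node vectors")
    path = tree.path_array(target)
    signs = tree.signs(target)
    z = model.inner[path] @ np.asarray(context_vector)
    return float(np.prod(_sigmoid(signs * z)))


def hs_gradient_step(
    model: EmbeddingModel,
    tree: HuffmanTree,
    target: str,
    context_vector: np.ndarray,
    lr: float,
) -> tuple[np.ndarray, float]:
    """One SGD step on -log P(target | context).

    Updates the inner-node vectors on the target's path in place and
    returns (gradient w.r.t. context_vector, loss before the step). The
    context gradient is computed at the pre-update inner vectors, as in
    simultaneous SGD. ``lr`` may be 0 to evaluate the gradient only.
    """
    if model.inner is None:
        raise ValueError("model carries no inner-node vectors")
    c = np.asarray(context_vector)
    path = tree.path_array(target)
    signs = tree.signs(target)
    X = model.inner[path]                      # (L, dim)
    z = X @ c
    f = _sigmoid(signs * z)
    loss = float(-np.sum(np.log(f)))
    g = -signs * (1.0 - f)                     # dL/dz_k
    grad_context = X.T @ g
    if lr != 0.0:
        model.inner[path] -= (lr * g)[:, None] * c
    return grad_context, loss


def skipgram_pairs(
    doc: Sequence[int], window: int
) -> list[tuple[int, int]]:
    """Enumerate (center, target) index pairs for Skip-gram on one document."""
    pairs = []
    n = len(doc)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        for j in range(lo, hi):
            if j != i:
                pairs.append((doc[i], doc[j]))
    return pairs


def cbow_contexts(
    doc: Sequence[int], window: int
) -> list[tuple[list[int], int]]:
    """Enumerate (context indices, center) pairs for CBOW on one document."""
    out = []
    n = len(doc)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        ctx = [doc[j] for j in range(lo, hi) if j != i]
        if ctx:
            out.append((ctx, doc[i]))
    return out


def train(
    corpus: Iterable[Sequence[str]],
    vocab: Vocabulary,
    tree: HuffmanTree,
    config: TrainingConfig,
) -> EmbeddingModel:
    """Train an embedding model over a corpus of token lists.

    Out-of-vocabulary tokens are skipped. Word vectors are initialized
    uniformly in [-0.5/dim, +0.5/dim]; inner-node vectors start at zero.
    The learning rate decays linearly from initial_lr to min_lr over
    epochs * corpus tokens. Identical corpus, config and seed give a
    bitwise-identical model. The per-epoch mean negative log probability is
    recorded on ``model.epoch_losses``.
    """
    rng = np.random.default_rng(config.seed)
    docs = [
        np.asarray([vocab.index(t) for t in doc if t in vocab], dtype=np.int64)
        for doc in corpus
    ]
    docs = [d for d in docs if len(d) > 0]
    total_tokens = sum(len(d) for d in docs)
    if total_tokens == 0:
        raise ValueError("empty corpus: no in-vocabulary token")

    dim = config.dim
    V = len(vocab)
    W = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))
    inner = np.zeros((max(tree.inner_node_count, 1), dim))
    model = EmbeddingModel(list(vocab.words), W, inner)

    # per-index path/sign arrays (avoids dict lookups in the loop)
    paths = [tree.path_array(w) for w in vocab.words]
    signs = [tree.signs(w) for w in vocab.words]

    keep_prob = None
    if config.subsample_threshold > 0:
        freq = np.asarray(vocab.frequencies, dtype=np.float64) / vocab.total_count
        ratio = config.subsample_threshold / freq
        keep_prob = np.minimum(1.0, np.sqrt(ratio) + ratio)

    lr_span = config.initial_lr - config.min_lr
    total_steps = config.epochs * total_tokens
    window = config.window
    is_skipgram = config.architecture == "skipgram"
    processed = 0

    for _epoch in range(config.epochs):
        loss_sum = 0.0
        loss_n = 0
        for doc in docs:
            if keep_prob is not None:
                doc = doc[rng.random(len(doc)) < keep_prob[doc]]
            n = len(doc)
            for i in range(n):
                lr = config.initial_lr - lr_span * (processed / total_steps)
                processed += 1
                center = doc[i]
                lo = i - window if i - window > 0 else 0
                hi = i + window + 1 if i + window + 1 < n else n
                if hi - lo <= 1:
                    continue
                if is_skipgram:
                    c = W[center]
                    for j in range(lo, hi):
                        if j == i:
                            continue
                        tgt = doc[j]
                        path, sgn = paths[tgt], signs[tgt]
                        X = inner[path]
                        f = _sigmoid(sgn * (X @ c))
                        loss_sum -= float(np.sum(np.log(f)))
                        loss_n += 1
                        g = -sgn * (1.0 - f)
                        grad_c = X.T @ g
                        inner[path] -= (lr * g)[:, None] * c
                        W[center] = c = c - lr * grad_c
                else:
                    ctx = np.concatenate((doc[lo:i], doc[i + 1 : hi]))
                    c = W[ctx].mean(axis=0)
                    path, sgn = paths[center], signs[center]
                    X = inner[path]
                    f = _sigmoid(sgn * (X @ c))
                    loss_sum -= float(np.sum(np.log(f)))
                    loss_n += 1
                    g = -sgn * (1.0 - f)
                    grad_c = X.T @ g
                    inner[path] -= (lr * g)[:, None] * c
                    # exact gradient of the mean: each context word gets 1/|ctx|;
                    # subtract.at handles repeated context indices correctly
                    np.subtract.at(W, ctx, lr * grad_c / len(ctx))
        model.epoch_losses.append(loss_sum / max(loss_n, 1))

    return model
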