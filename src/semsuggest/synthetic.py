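"""Synthetic corpora and toy ontologies with planted structure.

Every other module is testable without downloads: the synonym-corpus
generator plants interchangeable word groups that share contexts (the
distributional-hypothesis signal the trainer must recover), the phrase
generator plants high-frequency bigrams that must clear the collocation
score, and the ontology generator builds small is_a trees whose term
counts decrease strictly with depth so IC similarities behave like those
of a real corpus-annotated ontology. All generators are pure functions of
their parameters and seed.

These fixtures do not emulate real abstracts: token order within a
document is exchangeable, vocabularies are disjoint by construction and
there is no morphology — see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Document
from .ontosim import OntologyGraph, TermFrequencyTable

__all__ = [
    "SynonymSpec",
    "generate_synonym_corpus",
    "generate_phrase_corpus",
    "generate_toy_ontology",
    "write_obo",
]


def _default_groups() -> tuple[frozenset[str], ...]:
    return tuple(
        frozenset(f"syn{g}_{i}" for i in range(3)) for g in range(10)
    )


@dataclass(frozen=True)
class SynonymSpec:
    """Planted-synonym corpus: groups of interchangeable words.

    Each document belongs to one group; target words are drawn uniformly
    from the group, context words from the group's dedicated context
    vocabulary, with an admixture of shared background noise. A fraction
    ``context_overlap`` of context draws comes instead from the pooled
    context vocabulary of all groups — mimicking the generic vocabulary
    real prose shares across topics. That admixture is what makes the
    planted structure identifiable: it smears each context word's
    co-occurrence profile across groups while the synonyms keep pure
    profiles, so a synonym's nearest neighbour is a same-group synonym
    rather than one of its own context words. With ``context_overlap = 0``
    context words become distributional twins of their group's synonyms
    and top-1 recovery degrades gracefully.
    """

    groups: tuple[frozenset[str], ...] = field(default_factory=_default_groups)
    n_docs: int = 2000
    doc_length: int = 8
    context_vocab_per_group: int = 5
    background_vocab: int = 20
    target_prob: float = 0.4
    noise_prob: float = 0.1
    context_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self):
        all_words = [w for g in self.groups for w in g]
        if len(all_words) != len(set(all_words)):
            raise ValueError("synonym groups must be disjoint")
        if self.n_docs < 1 or self.doc_length < 1:
            raise ValueError("n_docs and doc_length must be >= 1")
        if not 0 <= self.target_prob + self.noise_prob <= 1:
            raise ValueError("target_prob + noise_prob must lie in [0, 1]")
        if not 0 <= self.context_overlap <= 1:
            raise ValueError("context_overlap must lie in [0, 1]")


def generate_synonym_corpus(spec: SynonymSpec) -> list[Document]:
    """Sample documents with planted synonym-group structure."""
    rng = np.random.default_rng(spec.seed)
    groups = [sorted(g) for g in spec.groups]
    ctx = [
        [f"ctx{g}_{i}" for i in range(spec.context_vocab_per_group)]
        for g in range(len(groups))
    ]
    pooled = [w for words in ctx for w in words]
    noise = [f"bg_{i}" for i in range(spec.background_vocab)]
    docs: list[Document] = []
    for d in range(spec.n_docs):
        g = int(rng.integers(len(groups)))
        tokens: list[str] = []
        for _ in range(spec.doc_length):
            u = rng.random()
            if u < spec.target_prob:
                tokens.append(groups[g][int(rng.integers(len(groups[g])))])
            elif u < spec.target_prob + spec.noise_prob and noise:
                tokens.append(noise[int(rng.integers(len(noise)))])
            elif rng.random() < spec.context_overlap:
                tokens.append(pooled[int(rng.integers(len(pooled)))])
            else:
                tokens.append(ctx[g][int(rng.integers(len(ctx[g])))])
        docs.append(Document(doc_id=str(d), text=" ".join(tokens)))
    return docs


def generate_phrase_corpus(
    planted_bigrams: Sequence[tuple[str, str]],
    background_vocab: int = 300,
    n_docs: int = 100,
    doc_length: int = 20,
    bigrams_per_doc: int = 3,
    seed: int = 0,
) -> list[Document]:
    """Sample documents in which the planted bigrams recur adjacently.

    Each document interleaves ``bigrams_per_doc`` planted pairs with filler
    drawn uniformly from a background vocabulary large enough that chance
    adjacent repetitions stay at or below the discounting coefficient, so
    the collocation filter at default settings recovers exactly the planted
    set.
    """
    rng = np.random.default_rng(seed)
    planted = list(planted_bigrams)
    filler = [f"w{i}" for i in range(background_vocab)]
    docs: list[Document] = []
    for d in range(n_docs):
        tokens = [filler[int(i)] for i in rng.integers(len(filler), size=doc_length)]
        # insert planted pairs at spaced slots so they never touch each other
        slots = rng.choice(
            np.arange(len(tokens) + 1), size=min(bigrams_per_doc, len(planted)),
            replace=False,
        )
        picks = rng.integers(len(planted), size=len(slots))
        for slot, pick in sorted(zip(slots.tolist(), picks.tolist()), reverse=True):
            tokens[slot:slot] = list(planted[pick])
        docs.append(Document(doc_id=str(d), text=" ".join(tokens)))
    return docs


def generate_toy_ontology(
    depth: int = 3,
    branching: int = 2,
    seed: int = 0,
    extra_parent_prob: float = 0.0,
    count_base: int = 4,
) -> tuple[OntologyGraph, TermFrequencyTable]:
    """Build a small is_a hierarchy with depth-monotone corpus counts.

    The root's count equals the table total (P(root) = 1, IC 0); a term at
    depth d has count ``count_base ** (depth - d)``, strictly decreasing
    with depth, which keeps every Lin similarity inside [0, 1] without
    clamping and makes deeper common ancestors strictly more informative.
    With ``extra_parent_prob`` > 0 some non-root terms gain a second parent
    on the previous level, turning the tree into a proper DAG.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    parents: dict[str, frozenset[str]] = {}
    counts: dict[str, int] = {}
    levels: list[list[str]] = []

    root = "T:0000000"
    terms[root] = ("root term", frozenset())
    parents[root] = frozenset()
    counts[root] = count_base ** (depth - 1)
    levels.append([root])

    serial = 1
    for d in range(1, depth):
        level: list[str] = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                tid = f"T:{serial:07d}"
                serial += 1
                ps = {parent}
                if extra_parent_prob > 0 and len(levels[d - 1]) > 1:
                    if rng.random() < extra_parent_prob:
                        other = levels[d - 1][int(rng.integers(len(levels[d - 1])))]
                        ps.add(other)
                terms[tid] = (f"term {tid[2:].lstrip('0') or '0'} depth {d}", frozenset())
                parents[tid] = frozenset(ps)
                counts[tid] = count_base ** (depth - 1 - d)
                level.append(tid)
        levels.append(level)

    graph = OntologyGraph(terms, parents, name="toy")
    freq = TermFrequencyTable(counts=counts, total=counts[root])
    return graph, freq


def write_obo(
    graph: OntologyGraph, path: str | Path, ontology_name: str = "toy"
) -> None:
    """Serialize an OntologyGraph as a minimal OBO 1.4 stanza file."""
    lines = [f"format-version: 1.4", f"ontology: {ontology_name}", ""]
    for tid in sorted(graph.terms()):
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {graph.label(tid)}")
        for syn in sorted(graph.synonyms(tid)):
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(graph.parents(tid)):
            lines.append(f"is_a: {parent} ! {graph.label(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
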