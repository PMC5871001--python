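"""Ontology-based information-content similarity (Resnik and Lin).

A term T's information content is IC(T) = -ln P(T), with P(T) the term's
relative frequency in a text corpus. The Resnik similarity of two terms is
the maximum IC over their common subsumers (is_a ancestors, each term
subsuming itself); Lin's similarity rescales it to [0, 1]:

    Sim_Lin(T1, T2) = 2 * Sim_Resnik(T1, T2) / (IC(T1) + IC(T2)).

Frequencies come from a flat term-frequency table (string counts in a
corpus); optionally counts can be propagated up the DAG (each term's count
becomes the sum over its subtree), the classic corpus-IC construction.
Used here to score how semantically close suggested queries are to the
original query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .corpus import PHRASE_DELIMITER

__all__ = [
    "OntologyGraph",
    "TermFrequencyTable",
    "SimilarityRow",
    "SimilarityReport",
    "OntologyError",
    "NoCommonSubsumerError",
    "parse_obo",
    "resnik",
    "lin",
    "match_to_ontology",
    "evaluate",
]


class OntologyError(ValueError):
    """Malformed ontology input (cycles, missing ids, zero-count subsumers)."""


class NoCommonSubsumerError(OntologyError):
    """The two terms share no ancestor, so IC similarity is undefined."""


class OntologyGraph:
    """Terms with labels/synonyms and an acyclic is_a hierarchy.

    ``parents`` maps a term id to its direct is_a parents; ancestor queries
    follow these edges transitively. Label and synonym lookup is
    case-insensitive.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, frozenset[str]]],
        parents: Mapping[str, frozenset[str]],
        name: str = "",
    ):
        self.name = name
        self._terms = dict(terms)
        self._parents = {t: frozenset(parents.get(t, ())) for t in self._terms}
        dag = nx.DiGraph()
        dag.add_nodes_from(self._terms)
        for child, ps in self._parents.items():
            for p in ps:
                if p not in self._terms:
                    raise OntologyError(f"is_a target {p!r} is not a term")
                dag.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyError(f"is_a cycle detected: {cycle}")
        self._dag = dag
        self._label_index: dict[str, str] = {}
        self._synonym_index: dict[str, str] = {}
        for tid, (label, synonyms) in self._terms.items():
            self._label_index.setdefault(label.lower(), tid)
            for syn in synonyms:
                self._synonym_index.setdefault(syn.lower(), tid)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def terms(self) -> Iterable[str]:
        return self._terms.keys()

    def label(self, term_id: str) -> str:
        return self._terms[term_id][0]

    def synonyms(self, term_id: str) -> frozenset[str]:
        return self._terms[term_id][1]

    def parents(self, term_id: str) -> frozenset[str]:
        return self._parents[term_id]

    def subsumers(self, term_id: str) -> set[str]:
        """The term itself plus all its is_a ancestors."""
        if term_id not in self._terms:
            raise KeyError(f"unknown term id: {term_id}")
        return {term_id} | nx.descendants(self._dag, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms that the given term subsumes (itself included)."""
        return {term_id} | nx.ancestors(self._dag, term_id)

    def find_label(self, text: str) -> str | None:
        """Case-insensitive exact match against labels, then synonyms."""
        key = text.lower()
        return self._label_index.get(key) or self._synonym_index.get(key)

    def roots(self) -> set[str]:
        return {t for t, ps in self._parents.items() if not ps}


@dataclass(frozen=True)
class TermFrequencyTable:
    """Corpus counts per term id; P(T) = count(T) / total."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total must be positive")
        for t, c in self.counts.items():
            if c < 0 or c > self.total:
                raise ValueError(f"count for {t!r} outside [0, total]")

    def count(self, term_id: str) -> int:
        return self.counts.get(term_id, 0)

    def probability(self, term_id: str) -> float:
        return self.count(term_id) / self.total

    def propagated(self, graph: OntologyGraph) -> "TermFrequencyTable":
        """Classic Resnik propagation: each term's count becomes the sum of
        raw counts over all terms it subsumes (itself included)."""
        new_counts = {
            t: sum(self.counts.get(d, 0) for d in graph.descendants(t))
            for t in graph.terms()
        }
        return TermFrequencyTable(counts=new_counts, total=self.total)

    @classmethod
    def from_tsv(
        cls, path: str | Path, total: int, graph: OntologyGraph | None = None
    ) -> "TermFrequencyTable":
        """Read a two-column TSV (term string or id, count). When a graph is
        given, first-column strings that are not term ids are resolved
        through its label/synonym index."""
        counts: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                key, value = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"line {lineno}: expected two TSV columns") from exc
            term_id = key
            if graph is not None and key not in graph:
                resolved = graph.find_label(key)
                if resolved is not None:
                    term_id = resolved
            counts[term_id] = counts.get(term_id, 0) + int(value)
        return cls(counts=counts, total=total)


def parse_obo(path: str | Path, name: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an OntologyGraph.

    Captures id, name, synonyms and is_a of every [Term] stanza; obsolete
    terms are skipped. Raises OntologyError on cyclic is_a hierarchies.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete terms by default
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    parents: dict[str, frozenset[str]] = {}
    for tid, data in graph.nodes(data=True):
        label = data.get("name", tid)
        synonyms = frozenset(
            _synonym_text(s) for s in data.get("synonym", ())
        )
        terms[tid] = (label, synonyms)
    for tid in graph.nodes:
        ps = frozenset(
            v for _, v, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        parents[tid] = ps & terms.keys()
    return OntologyGraph(terms, parents, name=name or Path(path).stem)


def _synonym_text(synonym_line: str) -> str:
    # OBO synonym lines look like: "salinity stress" EXACT []
    if synonym_line.startswith('"'):
        end = synonym_line.find('"', 1)
        if end > 0:
            return synonym_line[1:end]
    return synonym_line


def _information_content(
    term_id: str, freq: TermFrequencyTable, role: str
) -> float:
    count = freq.count(term_id)
    if count == 0:
        raise OntologyError(
            f"{role} {term_id!r} has zero corpus count; IC undefined"
        )
    return -math.log(count / freq.total) + 0.0  # avoid -0.0 at P = 1


def resnik(
    t1: str, t2: str, graph: OntologyGraph, freq: TermFrequencyTable
) -> float:
    """Max information content over common subsumers of t1 and t2.

    Each term subsumes itself, so resnik(t, t) = IC(t). Symmetric and
    non-negative (P <= 1). Raises NoCommonSubsumerError when the terms
    share no ancestor, OntologyError when the maximizing subsumer (the
    rarest common one) has a zero count.
    """
    common = graph.subsumers(t1) & graph.subsumers(t2)
    if not common:
        raise NoCommonSubsumerError(f"{t1} and {t2} share no subsumer")
    # the rarest subsumer maximizes -ln P; a zero count would dominate
    best = min(common, key=freq.count)
    return _information_content(best, freq, "common subsumer")


def best_subsumer(
    t1: str, t2: str, graph: OntologyGraph, freq: TermFrequencyTable
) -> str:
    """The common subsumer realizing the Resnik maximum (rarest common)."""
    common = graph.subsumers(t1) & graph.subsumers(t2)
    if not common:
        raise NoCommonSubsumerError(f"{t1} and {t2} share no subsumer")
    return min(common, key=lambda t: (freq.count(t), t))


def lin(
    t1: str, t2: str, graph: OntologyGraph, freq: TermFrequencyTable
) -> float:
    """Lin similarity 2*Sim_Resnik / (IC(t1) + IC(t2)), clamped to [0, 1].

    lin(t, t) = 1 whenever P(t) < 1. With a flat (non-propagated) frequency
    table a subsumer can be rarer than its descendants, pushing the raw
    ratio above 1; the value is clamped to preserve the 0-1 scale.
    Raises OntologyError when IC(t1) + IC(t2) = 0 (both terms have P = 1).
    """
    numerator = 2.0 * resnik(t1, t2, graph, freq)
    denom = _information_content(t1, freq, "term") + _information_content(
        t2, freq, "term"
    )
    if denom == 0.0:
        raise OntologyError(
            f"both {t1} and {t2} have probability 1; Lin denominator is zero"
        )
    return min(1.0, max(0.0, numerator / denom))


def match_to_ontology(
    suggestion: str, graphs: Sequence[OntologyGraph]
) -> tuple[str, OntologyGraph] | None:
    """Resolve a suggestion string to a term id.

    Underscore phrase delimiters map back to spaces; matching is
    case-insensitive and exact, labels before synonyms, and the first graph
    in the configured order wins. Returns (term id, graph) or None.
    """
    text = suggestion.replace(PHRASE_DELIMITER, " ")
    for graph in graphs:
        tid = graph.find_label(text)
        if tid is not None:
            return tid, graph
    return None


@dataclass(frozen=True)
class SimilarityRow:
    query: str
    suggestion: str
    query_term: str
    suggestion_term: str
    subsumer: str
    ontology: str
    sim_resnik: float
    sim_lin: float
    clamped: bool = False


@dataclass
class SimilarityReport:
    """Per-suggestion similarity rows plus recomputable aggregates."""

    rows: list[SimilarityRow] = field(default_factory=list)
    skipped_queries: list[str] = field(default_factory=list)

    @property
    def mean_lin(self) -> float:
        return (
            sum(r.sim_lin for r in self.rows) / len(self.rows)
            if self.rows
            else float("nan")
        )

    def fraction_above(self, threshold: float = 0.8) -> float:
        if not self.rows:
            return float("nan")
        return sum(1 for r in self.rows if r.sim_lin > threshold) / len(self.rows)

    @property
    def min_lin(self) -> float:
        return min((r.sim_lin for r in self.rows), default=float("nan"))

    def to_tsv(self) -> str:
        header = (
            "query\tsuggestion\tquery_term\tsuggestion_term\tsubsumer\t"
            "ontology\tsim_resnik\tsim_lin\tclamped"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                f"{r.query}\t{r.suggestion}\t{r.query_term}\t{r.suggestion_term}"
                f"\t{r.subsumer}\t{r.ontology}\t{r.sim_resnik:.6f}\t{r.sim_lin:.6f}"
                f"\t{int(r.clamped)}"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "rows": [r.__dict__ for r in self.rows],
            "skipped_queries": list(self.skipped_queries),
            "mean_lin": self.mean_lin,
            "fraction_above_0.8": self.fraction_above(0.8),
            "min_lin": self.min_lin,
        }


def evaluate(
    queries: Sequence[str],
    model,
    graphs: Sequence[OntologyGraph],
    freq: TermFrequencyTable,
    top_n: int = 10,
) -> SimilarityReport:
    """Score the top-n suggestions of each query by Lin similarity.

    For every query that matches an ontology term, its top-n suggestions
    are matched in turn; matched pairs are scored with Sim_Lin against the
    original term. Queries with no ontology match (or no in-vocabulary
    vector) are reported as skipped.
    """
    from .suggest import OutOfVocabularyError, top_k

    if not queries:
        raise ValueError("queries must be non-empty")
    report = SimilarityReport()
    for query in queries:
        matched = match_to_ontology(query, graphs)
        if matched is None:
            report.skipped_queries.append(query)
            continue
        qid, qgraph = matched
        try:
            suggestions = top_k(model, query, k=top_n)
        except OutOfVocabularyError:
            report.skipped_queries.append(query)
            continue
        for term, _score in suggestions:
            hit = match_to_ontology(term, graphs)
            if hit is None:
                continue
            sid, sgraph = hit
            if sgraph is not qgraph:
                continue  # IC is only comparable within one hierarchy
            try:
                sim_r = resnik(qid, sid, qgraph, freq)
                sub = best_subsumer(qid, sid, qgraph, freq)
                raw = 2.0 * sim_r / (
                    _information_content(qid, freq, "term")
                    + _information_content(sid, freq, "term")
                )
            except OntologyError:
                continue
            report.rows.append(
                SimilarityRow(
                    query=query,
                    suggestion=term.replace(PHRASE_DELIMITER, " "),
                    query_term=qid,
                    suggestion_term=sid,
                    subsumer=sub,
                    ontology=qgraph.name,
                    sim_resnik=sim_r,
                    sim_lin=min(1.0, max(0.0, raw)),
                    clamped=raw > 1.0,
                )
            )
    return report
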