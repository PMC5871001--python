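"""Resnik and Lin information-content similarity on a toy ontology.

Generates a 3-level is_a tree with corpus counts that decrease with depth
(root count = corpus total, so P(root) = 1). Terms sharing a deeper — and
hence rarer, more informative — ancestor come out more similar.
"""

from semsuggest import generate_toy_ontology, lin, resnik

graph, freq = generate_toy_ontology(depth=3, branching=2, seed=1)
root = next(iter(graph.roots()))
mid_a, mid_b = sorted(t for t in graph.terms() if graph.parents(t) == {root})
leaves_a = sorted(t for t in graph.terms() if graph.parents(t) == {mid_a})
leaves_b = sorted(t for t in graph.terms() if graph.parents(t) == {mid_b})

pairs = [
    ("same term", leaves_a[0], leaves_a[0]),
    ("siblings (parent at depth 1)", leaves_a[0], leaves_a[1]),
    ("cousins (only the root shared)", leaves_a[0], leaves_b[0]),
]
for name, a, b in pairs:
    print(f"{name}: Resnik {resnik(a, b, graph, freq):.3f}, "
          f"Lin {lin(a, b, graph, freq):.3f}")
# a term is maximally similar to itself (Lin 1.0); siblings share an
# informative parent (0 < Lin < 1); cousins share only the root, whose
# P = 1 carries no information (Lin 0.0)
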