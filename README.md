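# semsuggest

Corpus-based semantic query suggestion for life-science search frontends.

Full-text search over biological databases lives or dies by the keywords a
user happens to type: "salt stress" and "salinity stress" retrieve largely
disjoint abstract sets even though they mean the same thing. `semsuggest`
suggests alternative keyword queries learned directly from the text corpus
being searched — no query logs, no curated thesaurus — by exploiting the
distributional hypothesis: words that occur in similar contexts tend to
have similar meanings.

The package provides the full stack:

- **Corpus preparation** — Unicode tokenization that preserves database
  identifiers (`AT1G01010`, `Q9S7U2-2`), and collocation phrase mining with
  the discounted score
  `score(wᵢ, wⱼ) = (count(wᵢwⱼ) − δ) / (count(wᵢ)·count(wⱼ))`
  (defaults δ = 5, threshold 9·10⁻⁸, calibratable against ontology-term
  overlap), so multi-word concepts like *heading date* become single
  vocabulary entries.
- **Word-vector training** — CBOW and Skip-gram architectures with a
  hierarchical-softmax output layer over a Huffman tree built on word
  frequencies, giving `O(log₂|V|)` cost per probability evaluation:
  `P(w|c) = Πₖ σ(sₖ·⟨v_{nₖ}, c⟩)` over the word's tree path. Plain SGD,
  linear learning-rate decay, bitwise-reproducible for a fixed seed.
- **Suggestion** — exact top-k cosine-similarity scan over the vocabulary,
  with a compact binary model format (`QSM1`) for serving.
- **HTTP service** — `GET /api/v1/semanticsuggestion/<query>` returning
  `{"suggestions": [...]}` (top 5), embeddable in any search frontend.
- **Evaluation** — Resnik/Lin information-content similarity against OBO
  ontologies (GO, TO, ChEBI, ...):
  `Sim_Lin(T₁,T₂) = 2·max_{Tₛ}(−ln P(Tₛ)) / (−ln P(T₁) − ln P(T₂))` over
  common is_a subsumers Tₛ, with P(T) a term's relative corpus frequency.
- **Synthetic fixtures** — generators for planted-synonym corpora, planted
  phrase corpora and toy ontologies, so the whole stack is testable
  offline.

## Worked example

Train Skip-gram vectors on a generated corpus that plants 10 groups of 3
interchangeable words and ask for suggestions
(`python examples/02_train_and_suggest.py`):

```
|V| = 100, dim = 50
per-epoch mean -log P: [4.087, 3.897, 3.901, 3.907, 3.914]
top-5 suggestions for 'syn0_0':
  syn0_1     cosine 0.989
  syn0_2     cosine 0.986
  ctx0_3     cosine 0.892
  ctx0_1     cosine 0.828
  ctx0_2     cosine 0.826
```

The two planted synonyms of `syn0_0` rank first with cosine ≈ 0.99 — the
trainer recovered the planted interchangeability from context alone; the
group's own context words follow at a distance. The epoch loss (mean
negative log probability under the hierarchical softmax) drops sharply in
the first pass and then plateaus.

The other examples mine planted phrases (`01`), compute Resnik/Lin
similarities on a toy ontology (`03` — a term scores Lin 1.0 against
itself, 0.5 against a sibling, 0.0 when only the root is shared), serve
suggestions over real HTTP (`04`) and run the ontology-based quality
evaluation end to end (`05`).

A `semsuggest` console command exposes the same steps as subcommands
(`corpus`, `train`, `suggest`, `serve`, `evaluate`, `fixtures`); run
`semsuggest --help`.

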