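"""Train Skip-gram vectors on a planted-synonym corpus and query them.

The corpus plants 10 groups of 3 interchangeable words sharing per-group
context vocabulary. After training, the nearest cosine neighbours of a
group word should be its fellow group members — the query-suggestion
mechanism in miniature.
"""

from semsuggest import (
    SynonymSpec,
    TrainingConfig,
    build_huffman,
    build_vocabulary,
    generate_synonym_corpus,
    top_k,
    train,
)

spec = SynonymSpec(seed=0)
docs = generate_synonym_corpus(spec)
tokens = [d.text.split() for d in docs]
vocab = build_vocabulary(tokens, min_count=1)
tree = build_huffman(vocab)
config = TrainingConfig(architecture="skipgram", dim=50, window=5, epochs=5, seed=0)
model = train(tokens, vocab, tree, config)

print(f"|V| = {len(vocab)}, dim = {config.dim}")
print("per-epoch mean -log P:", [round(x, 3) for x in model.epoch_losses])
for query in ["syn0_0", "syn4_1"]:
    print(f"top-5 suggestions for {query!r}:")
    for term, score in top_k(model, query, k=5):
        print(f"  {term:10s} cosine {score:.3f}")
# the top entries should be the query's fellow synonyms (e.g. syn0_1, syn0_2
# for syn0_0) with cosine close to 1; the epoch loss drops sharply in the
# first pass and then plateaus as SGD converges
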