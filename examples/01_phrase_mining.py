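"""Mine collocation phrases from a synthetic corpus with planted bigrams.

Builds a corpus in which ten word pairs recur adjacently, scores every
adjacent pair with the discounted collocation score
(count_ij - delta) / (count_i * count_j), and keeps pairs above the
threshold. With delta = 5 and threshold 9e-8 exactly the planted pairs
survive.
"""

from semsuggest import PhraseConfig, count_ngrams, extract_phrases, phrase_score
from semsuggest.synthetic import generate_phrase_corpus

planted = [(f"alpha{i}", f"beta{i}") for i in range(10)]
docs = generate_phrase_corpus(planted, seed=42)
stats = count_ngrams(docs)
config = PhraseConfig(delta=5.0, score_threshold=9e-8)
phrases = extract_phrases(stats, config)

print(f"corpus: {len(docs)} documents, {stats.total_tokens} tokens")
print(f"mined {len(phrases)} phrases (planted {len(planted)}):")
for wi, wj in sorted(phrases)[:5]:
    cij = stats.bigram_counts[(wi, wj)]
    s = phrase_score(cij, stats.unigram_counts[wi], stats.unigram_counts[wj], 5.0)
    print(f"  {wi} {wj}: count {cij}, score {s:.4f}")
print("recall:", len(phrases & set(planted)) / len(planted),
      " precision:", len(phrases & set(planted)) / len(phrases))
# a score of e.g. 0.03 means the pair co-occurs far above chance; recall and
# precision of 1.0 mean the filter recovered exactly the planted phrases
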