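# biomedqa

Question answering over a corpus of titled biomedical abstracts.

Biomedical researchers ask natural-language questions ("Which drug inhibits
neurodegeneration?", "What is the mechanism of action of abiraterone?") whose
answers are buried in abstract sentences. `biomedqa` is an end-to-end engine
that turns such a question into a weighted boolean keyword query, relaxes the
query iteratively until a search index returns documents, ranks the retrieved
sentences by an IDF-weighted relaxed word mover's distance over word/phrase
embeddings, filters factoid candidates by the question's focus entity type,
optionally reranks with a trainable sentence-pair classifier, and extracts
exact answer phrases.

## The core model

**Answer ranking.** Word mover's distance casts document similarity as
optimal transport between bag-of-embedding term distributions. Dropping the
demand-side constraint makes the optimum closed-form, and weighting the unique
question terms `I_Q` by inverse document frequency gives the ranking score

```
wRWMD(Q, A) = Σ_{i∈I_Q} w_i · max_{j∈I_A} cossim(v_i, v_j) / Σ_{k∈I_Q} w_k
```

where `v_i` are embedding vectors and `w_i = ln(N/df_i)` are corpus IDF
weights. Candidate sentences are sorted by this similarity, descending
(`1 − wRWMD` is the corresponding distance; both conventions give the same
order).

**Retrieval.** The query is a conjunction of *search constructs* — OR-groups
of one term's surface variants (an NP with its number variants and acronyms,
or a verb with its conjugations and nominalizations) — each weighted by

```
w_cons = (1/|ST|) [ Σ_{i∈V} w_i + Σ_{i∉V} min_j w_ij ]
```

(in-vocabulary disjuncts contribute their IDF; out-of-vocabulary ones the
minimum IDF over their tokens). Queries start maximally specific and are
relaxed greedily: verb groups are dropped first regardless of weight, then
the group with the least maximum weight loses its lowest-weight disjunct,
while groups matching recognized entities (the likely question focus) are
protected until everything else is a singleton.

**Trainable components.** A sequence-labeling classifier (dense / LSTM /
1-D-convolution encoders over fixed 40-position embedding sequences, with an
optional POS branch) marks question tokens as keywords to force-include in
the initial query; a sentence-pair classifier trained on one-positive /
pool-negatives data reranks the similarity-ranked candidates by answer
probability. Both are seeded, CPU-only numpy/scikit-learn implementations
behind pluggable backend contracts.

## Worked example

Everything runs offline on a seeded synthetic fixture (invented entities,
abstracts, and latent-direction embeddings):

```
$ biomedqa fixtures generate -o fx --seed 1
$ biomedqa index build fx/corpus.jsonl -o fx/index.json
indexed 50 documents -> fx/index.json
$ biomedqa ask "Which drug inhibits neurodegeneration?" \
    --index-path fx/index.json --embeddings fx/embeddings.txt \
    --gazetteer fx/gazetteer.tsv --top-k 2
{
 "answers": [
  {
   "doc_id": "doc0000",
   "entities": [{"surface": "zelorafenib", "type": "drug"}],
   "rank": 1,
   "rerank_prob": null,
   "score": 1.0,
   "sentence": "The drug zelorafenib inhibits neurodegeneration in cortical neurons.",
   "sentence_index": 1
  }
 ],
 "exact_answers": [
  {"path": "entity", "phrase": "zelorafenib", "score": 0.0, "sentence_rank": 1}
 ],
 "exhausted": false,
 "iterations": 0,
 "question": "Which drug inhibits neurodegeneration?"
}
```

Reading the output: the initial boolean query already matched documents
(`iterations: 0`, no relaxation needed); the answer sentence contains every
question term, so its similarity is exactly 1.0; the question's focus head
"drug" maps to the drug entity type, so only sentences carrying a drug
mention survive the focus filter, and the exact-answer stage returns the
unique drug entities of the top sentences in first-occurrence order.

`biomedqa eval fx/gold.json ...` scores a BioASQ-style gold file by mean
reciprocal rank (MRR = (1/N) Σ 1/rank(Qᵢ)) and Precision@1, with heuristic
gold-string alignment standing in for human judgment. `biomedqa
train-selector` and `biomedqa train-reranker` fit the supervised components
from JSONL annotation files.

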