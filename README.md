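# litkg

A toolkit for building and auditing **literature-derived biomedical
knowledge graphs**, modelled on the pipeline used to assemble a
hepatocellular-carcinoma knowledge graph from extractor output: noisy
subject–relation–object predications mined from abstracts, clinical
guidelines, trial registries and predication databases are filtered,
cross-verified, fused into canonical entities, stored as a graph and
quality-audited. It is written for text-mining and knowledge-graph
researchers who need the *machinery* of that pipeline — with ground
truth, so every stage is measurable — rather than access to the licensed
corpora behind any particular deployment.

## What it does

- **Predication I/O** — TSV/JSONL readers and writers for triples carrying
  the full extraction context (PMID, source, sentence, per-argument text
  name / standard name / id / type / character offsets), with strict
  offset validation; CoNLL-style BIO corpus I/O with repair-or-reject
  handling of invalid tag sequences; a YAML schema config (9 concepts,
  22-relation whitelist, 7 verifier concepts by default).
- **Conclusiveness filter** — removes triples extracted from question
  sentences ("Is excessive alcohol abuse one of the causes of
  hepatocellular carcinoma?" must not yield `causes(alcohol, HCC)`).
- **NER verifier** — a document-level attention BiLSTM-CRF tagger
  (numpy, hand-derived gradients, CRF decoded exactly). For token
  context vectors `h_i` the attention matrix is the rowwise softmax
  `a_ij = exp(score(h_i, h_j)) / Σ_k exp(score(h_i, h_k))` with four
  score variants (manhattan `W·|h_i−h_j|`, euclidean
  `W·(h_i−h_j)ᵀ(h_i−h_j)`, cosine, perceptron `tanh(W·[h_i; h_j])`),
  and `G = A·H` supplies document-level context so an entity is tagged
  consistently across sentences.
- **Verifier-agreement filter** — a triple survives only if both
  arguments were reproduced by the verifier with identical text name,
  start/end index, sentence and source (strict mode), or with arguments
  outside the verifier's type inventory exempted (type-scoped mode).
- **Fusion** — entities grouped by normalized standard name with surface
  forms kept as synonyms; cross-extractor names aligned by token-set
  Jaccard (`|A∩B|/|A∪B|`), auto-merged only at exactly 1, queued for
  review otherwise; conflicting types resolved by plurality vote with
  ties escalated.
- **Graph store** — canonical entities + deduplicated provenance-carrying
  edges; focus-entity statistics (direct = incident to the focus,
  indirect = the rest), two-hop hypothesis queries, and Neo4j
  bulk-import CSV export that round-trips exactly.
- **Evaluation** — seeded simple random sampling, pairwise annotator
  agreement (Jaccard over the sets marked TRUE), a six-category
  disagreement taxonomy with per-genre shares, and P/R/F arithmetic.
- **Synthetic fixtures** — a seeded generator of gold corpora and
  noise-corrupted simulated extractor output (boundary truncation, type
  errors, question rendering, spurious/passive/negated relations), fully
  bookkept so pipeline precision and recall are measurable.

See `docs/methods.md` for the models, parameters and design decisions.

## Worked example

```python
from litkg.synthetic import GenConfig, NoiseConfig, corrupt, end_to_end_benchmark, gen_gold

gold = gen_gold(GenConfig(n_docs=40, sentences_per_doc=5, seed=7))
noisy = corrupt(gold, NoiseConfig(p_question=0.15, p_boundary_truncation=0.15,
                                  p_passive_swap=0.10, p_spurious_relation=0.30,
                                  p_negation=0.30, seed=7))
print(end_to_end_benchmark(gold, noisy))
```

Running `python examples/01_generate_and_filter.py` (the same
computation) prints:

```
gold corpus: 40 docs, 400 mentions, 143 triples
simulated extractor output: 166 triples (107 corruptions applied)
after filtering: retained 113 of 166, removed 53
precision 0.699  recall 0.552
```

143 relational sentences yielded gold triples; the noise channels added
spurious/negated triples (166 extracted) and corrupted sentences and
mentions. The filters removed every question-sentence triple and every
triple whose arguments the simulated verifier failed to reproduce
verbatim; what remains is measured against gold. Precision below 1 comes
from swapped, spurious and negated triples that argument-level
verification cannot catch (exactly the relation-level error classes that
dominate manual audits); recall below 1 comes from question sentences
and truncated mentions. With all noise rates at zero the same pipeline
scores precision = recall = 1.0.

The other examples demonstrate training the verifier
(`02_train_verifier.py`), fusing and querying a graph with two-hop
hypotheses and Neo4j export (`03_fuse_and_graph.py`), and the quality
audit (`04_evaluate_quality.py`). A thin CLI mirrors the stages:
`litkg simulate | train-ner | tag | filter | fuse | stats | export |
evaluate`.

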