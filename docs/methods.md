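# Methods

`litkg` implements the pipeline by which a disease-centred knowledge graph
is assembled from the output of biomedical information-extraction systems:
predication records (subject–relation–object triples with sentence-level
provenance) are filtered, cross-verified against an independent named-entity
recognizer, fused into canonical entities, stored as a graph, and audited.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Record model and offsets

A predication triple carries its full extraction context: source document
id, source corpus (literature, UpToDate-style guideline, clinical-trial
registry, or a predication database), the sentence string, and for each
argument the surface text name, the preferred standard name, an opaque
entity id, an entity type, and character offsets within the sentence.

Character offsets are **0-based with an inclusive end index**:
`sentence[start:end+1] == text_name`. Most NLP tooling uses half-open
spans; the inclusive convention matches the "first/last character
position" semantics of the record format this toolkit consumes, and every
reader enforces the substring invariant (violations are collected into an
error report rather than silently dropped). Whether such records use 0- or
1-based indices is convention-dependent; this package fixes 0-based as its
own convention and documents it at the format boundary.

The schema defaults to nine concepts (drug — subsuming chemicals — DNA,
RNA, gene, protein, cell, disease, phenotypic abnormality, therapeutic
technique) and a 22-label relation whitelist. The concrete 22 labels are a
placeholder drawn from the UMLS Semantic Network relation vocabulary and
are expected to be overridden per deployment; only the inventory *size*
is meaningful to the defaults. The verifier subset is the seven concepts
a multi-type biomedical NER system typically covers (disease, drug,
protein, gene, DNA, RNA, cell).

## Conclusiveness filter

Triples extracted from interrogative sentences assert nothing ("Is
excessive alcohol abuse one of the causes of hepatocellular carcinoma?"
must not yield *causes(alcohol, hepatocellular carcinoma)*). "Question
sentence" is not a well-defined linguistic category at the string level,
so the rule is deliberately simple and configurable: a sentence is a
question iff its stripped text ends with `?`, or it opens with an
interrogative/auxiliary cue word (is/are/does/do/can/could/what/which/
who/how/why/when, case-insensitive, user-editable) while containing no
declarative terminal period. Parsing-based interrogative detection is out
of scope.

## Verifier agreement

A triple survives verification only if each argument has a mention,
produced independently by the NER verifier on the same sentence, that
agrees on all five compared attributes: text name, start index, end
index, sentence (string equality after whitespace normalization — the
rule is "the same", with no tolerance), and source. Removal reasons
distinguish a verifier that produced nothing for the sentence
(`verifier_missing`) from one that produced a conflicting span
(`attribute_mismatch`), because the two have different failure modes
upstream (coverage vs. boundary errors).

Two policies are first-class. `strict` applies the rule verbatim; it
necessarily removes triples whose arguments the verifier cannot type at
all (e.g. therapeutic techniques under a seven-type verifier).
`type_scoped` (the default) exempts such arguments and flags the triple
for the record instead; this is the only reading under which a graph can
retain therapeutic-technique entities while using a seven-type verifier.
Both behaviours are exposed because the per-argument scoping of the
original procedure is not recoverable from its description.

## Fusion

Entity mapping groups mentions by **normalized standard name** —
lowercase, punctuation stripped to spaces, whitespace-tokenized, as a
token *set* — rather than by entity id, because the same entity can carry
different ids and standard names across extractors. The canonical node
name is the most frequent raw standard name in the group (ties broken
lexicographically for determinism); all observed text names are retained
as synonyms; ids and provenance are unioned.

Entity alignment across extractors uses token-set Jaccard similarity.
Only an exact token-set match (similarity exactly 1 after normalization)
aligns automatically; any lower value — e.g. "Primary carcinoma of the
liver cells" vs "Hepatocellular Carcinoma", which share one token of a
seven-token union (1/7) — goes to a review queue for a human decision.
The toolkit never auto-resolves queue items; reviewed items can be merged
back by re-running fusion on the amended input. Jaccard on token sets
(not characters or strings) is the only reading under which "similarity
equal to 1" is a meaningful threshold.

Conflicting type observations are resolved by plurality vote; a tied top
count yields an unresolved entity that is excluded from the typed graph
and queued, along with every triple that touches it. Each input triple
therefore maps to exactly one deduplicated edge or one review item.

## Graph statistics and export

"Directly related" triples are edges incident to the designated focus
entity; everything else is indirect — the reading under which direct +
indirect = total holds by construction. Neighborhood statistics and the
two-hop hypothesis query (entities at undirected distance exactly two
from the focus, each pair carrying its two evidence edges) ignore edge
direction, while edges store their subject→object direction for export,
since relations like *treats* are directional but hypothesis browsing is
not.

Export writes the two-file CSV layout of the Neo4j offline bulk importer
(`name:ID,:LABEL,synonyms,ids,sources` / `:START_ID,:END_ID,:TYPE,pmids,
sentences,sources`), RFC-4180 quoted, list fields ';'-joined. A ';'
inside a value is backslash-escaped so that export→import is an exact
identity; a consumer feeding the files to `neo4j-admin import` unescapes
or avoids such values.

## The NER verifier

The verifier is a document-level attention BiLSTM-CRF sequence tagger,
implemented in numpy with hand-derived backpropagation (verified against
finite differences in the test suite).

*Token vectors.* Each token is the concatenation of a word embedding
(dim 24, random init, trainable; pretrained vectors are pluggable but not
required) and the final state of a small recurrent character encoder
(char embeddings dim 8, hidden dim 16). Optional extra features (POS,
chunk) are off by default.

*Encoder.* A BiLSTM (24 units per direction, d_h = 48) runs over the
whole document's token sequence, so context crosses sentence boundaries.

*Attention.* For tokens i, j the score is one of four variants:
manhattan `W·|h_i − h_j|` (W a d_h vector), euclidean
`W·(h_i − h_j)ᵀ(h_i − h_j)` (W scalar), cosine `W·cos(h_i, h_j)`
(W scalar; a zero-norm vector scores 0 — a removable singularity closed
by definition), and perceptron `tanh(W·[h_i; h_j])` (W a 2·d_h vector).
The published description lists the four variants without declaring
per-variant weight shapes or a winner; the shapes above and the
perceptron default (the only variant with a trainable interaction over
the concatenation) are this package's choices, all four selectable by
config. Rowwise softmax of the N×N score matrix gives the attention
matrix A (rows sum to 1), and G = A·H are the global vectors. Attention
spans the full document by default; a windowed mode caps the scope for
long documents.

*Output layers.* How local and global context combine before the output
layer is an open design point; here they are concatenated per token,
[h_t; g_t], then passed through a tanh hidden layer (dim 32) and a linear
projection to |T| = 2·|concepts|+1 BIO tag scores. A linear-chain CRF
decodes the best tag path (Viterbi, ties broken toward the lowest tag
index for determinism). BIO validity is enforced structurally: forbidden
transitions (and I- tags at sentence start) carry −∞ score, so decoded
output never needs repair.

*Training.* Plain SGD over per-document CRF negative log-likelihood,
**normalized per token** so step sizes are document-length-independent,
with global gradient-norm clipping at 5. Because of that normalization
the default learning rate is 0.5 (an unnormalized-loss SGD at rate ~0.05
takes equivalent steps on these document lengths); 30 epochs by default.
Training is deterministic for a fixed seed, and a saved model (single
JSON file) reloads with bit-identical predictions.

## Synthetic corpora

The generator emulates the study conditions at desk scale: documents of
5 sentences (≥2 required, so document-level attention is exercised), each
sentence carrying two entity mentions from a built-in
hepatocellular-carcinoma-flavoured lexicon (28 entities across all nine
concepts, with multiword, hyphenated and synonymous surface forms).
Sentences are 70% relational (asserting one gold triple), 15%
co-occurrence (two entities, no asserted relation) and 15% negation (an
explicitly denied relation) — fractions chosen once as a realistic mix
that gives the spurious- and negation-noise channels raw material.

Six corruption channels mirror the error taxonomy observed in real
extractor output: boundary truncation (a multiword mention loses its
trailing token, "TGF-beta receptor-2" → "TGF-beta receptor"), type
errors, interrogative rendering (a cue prefix plus terminal `?`, so the
channel is detectable by the conclusiveness rule's two signals), spurious
co-occurrence triples, passive subject/object swaps, and affirmative
triples lifted from negated sentences. Each channel draws one uniform
per candidate item regardless of its rate, so at a fixed seed the
corrupted set grows monotonically with each probability — that is what
makes the precision-monotonicity checks meaningful. All corruption is
bookkept, and with all rates at zero the output equals the gold exactly.

What the generator does **not** emulate: real lexical ambiguity (the
fixture vocabulary is separable by construction — entity tokens never
appear as filler), real sentence length and syntax, extractor-specific
error correlations, and corpus-scale statistics. A perfect score on the
synthetic benchmark therefore demonstrates that the machinery is correct
and trainable, not that it would match published corpus-level accuracy on
licensed data.

## Evaluation

Annotator agreement is the Jaccard index of the two teams' sets of
triples marked TRUE; two empty sets are defined to agree (value 1), since
the alternative breaks "equal sets → 1". Sampling for manual audit is
simple random sampling without replacement, seeded. The disagreement
report computes each category's share of all audited errors and each
genre's share within a category, rounding **half-up to two decimals**; a
truncation column is available for audit because some published tables
truncate instead (the two differ in cells like 14/188 = 7.4468… → 7.45
vs 7.44), and internal consistency is preferred over mimicking mixed
rounding. The manual-audit accuracy (marked-correct / sampled) is a
separate helper from pairwise agreement; the two are related but not
interchangeable, and the package exposes both without claiming either is
the other.

## Problem sizes

Defaults used by the test suite and the acceptance script: NER benchmark
200 documents (160 train / 40 held out), 30 epochs, ~2.6 minutes on one
CPU; CRF-vs-enumeration 200 random instances with N ≤ 5, |T| ≤ 4;
pipeline noise grids 60 documents × 3 rates × 6 channels. These sizes
were chosen as the package's own desk-scale defaults; all are
configurable.

## Known limitations

- The relation whitelist ships as a placeholder; real deployments must
  supply their own 22 (or other) labels.
- The question rule is surface-level and English-only.
- Fusion trusts standard names; systematically wrong standard names from
  an extractor merge wrong entities (mitigated only by the review queue).
- The numpy NER trainer is single-threaded and desk-scale by design; it
  is not a GPU training stack and makes no corpus-scale claims.
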