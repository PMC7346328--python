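"""Seeded synthetic corpora with known ground truth and controllable noise.

Real construction of a literature knowledge graph needs licensed corpora,
a relation extractor and human review; none of those are testable inputs.
This module generates small hepatocellular-carcinoma-flavoured documents
with gold entity mentions and gold predication triples, then corrupts
copies of them through the same noise channels observed in real extractor
output: boundary truncation of multiword mentions, wrong entity types,
interrogative sentences, spurious co-occurrence relations, passive
subject/object swaps, and affirmative triples lifted from negated
sentences.  Every corruption is bookkept, so pipeline precision/recall
can be measured against ground truth.

Sentences come in three kinds — relational (carrying a gold triple),
co-occurrence (two entities, no asserted relation) and negation (an
explicitly denied relation) — in a 70/15/15 mix, so the spurious and
negation channels have realistic raw material to act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .filters import VerifierPolicy, run_filter_pipeline
from .records import EntityMention, PredicationTriple, SentenceRecord, TaggedDocument
from .schema import SchemaConfig

__all__ = [
    "LexiconEntry",
    "DEFAULT_LEXICON",
    "GenConfig",
    "NoiseConfig",
    "GoldBundle",
    "CorruptedBundle",
    "gen_gold",
    "corrupt",
    "end_to_end_benchmark",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One entity: a standard name, its surface forms, type and id."""

    standard_name: str
    surfaces: Tuple[str, ...]
    concept: str
    entity_id: str


# Small built-in biomedical-flavoured lexicon.  Multiword and hyphenated
# surfaces make boundary-truncation noise meaningful; several entities have
# more than one surface form so fusion has synonyms to collect.  Surface
# tokens are disjoint from the filler vocabulary, which keeps the NER
# benchmark corpus separable by construction.
DEFAULT_LEXICON: Tuple[LexiconEntry, ...] = (
    LexiconEntry("Hepatocellular Carcinoma", ("hepatocellular carcinoma", "HCC", "hepatoma"), "disease", "C0001"),
    LexiconEntry("Liver Cirrhosis", ("liver cirrhosis", "cirrhosis"), "disease", "C0002"),
    LexiconEntry("Hepatitis B", ("hepatitis B", "chronic hepatitis B"), "disease", "C0003"),
    LexiconEntry("Hepatitis A", ("hepatitis A",), "disease", "C0004"),
    LexiconEntry("Sorafenib", ("sorafenib",), "drug", "C0101"),
    LexiconEntry("Doxorubicin", ("doxorubicin",), "drug", "C0102"),
    LexiconEntry("Cisplatin", ("cisplatin",), "drug", "C0103"),
    LexiconEntry("Glucagon", ("glucagon",), "drug", "C0104"),
    LexiconEntry("Lenvatinib", ("lenvatinib",), "drug", "C0105"),
    LexiconEntry("TP53", ("p53 gene", "TP53 gene"), "gene", "C0201"),
    LexiconEntry("CTNNB1", ("CTNNB1", "beta-catenin gene"), "gene", "C0202"),
    LexiconEntry("TERT", ("TERT promoter",), "gene", "C0203"),
    LexiconEntry("TGF-beta receptor 2", ("TGF-beta receptor-2",), "protein", "C0301"),
    LexiconEntry("Alpha-fetoprotein", ("alpha-fetoprotein", "AFP protein"), "protein", "C0302"),
    LexiconEntry("Growth hormone receptor", ("growth hormone receptor",), "protein", "C0303"),
    LexiconEntry("Hepatocyte", ("hepatocyte", "liver cells"), "cell", "C0401"),
    LexiconEntry("T Cell", ("T lymphocyte",), "cell", "C0402"),
    LexiconEntry("Hepatic Stellate Cell", ("hepatic stellate cell",), "cell", "C0403"),
    LexiconEntry("Mitochondrial DNA", ("mitochondrial DNA",), "DNA", "C0501"),
    LexiconEntry("HBV DNA", ("HBV DNA",), "DNA", "C0502"),
    LexiconEntry("MicroRNA-21", ("microRNA-21", "miR-21"), "RNA", "C0601"),
    LexiconEntry("LncRNA HULC", ("lncRNA HULC",), "RNA", "C0602"),
    LexiconEntry("Jaundice", ("jaundice",), "phenotypic_abnormality", "C0701"),
    LexiconEntry("Ascites", ("ascites",), "phenotypic_abnormality", "C0702"),
    LexiconEntry("Weight Loss", ("weight loss",), "phenotypic_abnormality", "C0703"),
    LexiconEntry("Radiofrequency Ablation", ("radiofrequency ablation",), "therapeutic_technique", "C0801"),
    LexiconEntry("Liver Transplantation", ("liver transplantation",), "therapeutic_technique", "C0802"),
    LexiconEntry("Transarterial Chemoembolization", ("transarterial chemoembolization", "TACE"), "therapeutic_technique", "C0803"),
)

# Sentence skeletons; ~ marks the two entity slots.  None of them opens
# with an interrogative cue word, so gold sentences are declarative.
_RELATIONAL_TEMPLATES = (
    ("recent", "clinical", "data", "suggest", "that", "~", "may", "be", "linked", "to", "~", "in", "this", "setting"),
    ("the", "present", "cohort", "showed", "that", "~", "strongly", "influences", "~", "among", "enrolled", "subjects"),
    ("several", "independent", "reports", "describe", "an", "effect", "of", "~", "on", "~", "under", "routine", "conditions"),
    ("our", "follow", "up", "confirmed", "a", "reproducible", "interaction", "between", "~", "and", "~", "across", "centers"),
)
_COOCCURRENCE_TEMPLATES = (
    ("both", "~", "and", "~", "were", "recorded", "for", "every", "subject", "at", "baseline"),
    ("the", "screening", "panel", "measured", "~", "alongside", "~", "without", "further", "interpretation"),
)
_NEGATION_TEMPLATES = (
    ("~", "did", "not", "alter", "~", "according", "to", "the", "blinded", "review"),
    ("no", "evidence", "connected", "~", "with", "~", "after", "adjustment", "for", "confounders"),
)

_SOURCES_CYCLE = ("literature", "uptodate", "clinicaltrials", "semmeddb")


@dataclass(frozen=True)
class GenConfig:
    """Sizes and vocabulary for gold-corpus generation."""

    n_docs: int = 10
    sentences_per_doc: int = 5
    seed: int = 0
    schema: SchemaConfig = field(default_factory=SchemaConfig.default)
    lexicon: Tuple[LexiconEntry, ...] = DEFAULT_LEXICON
    concepts: Optional[Tuple[str, ...]] = None  # restrict lexicon; None = all
    kind_weights: Tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.sentences_per_doc < 2:
            raise ValueError("documents must span at least 2 sentences")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel corruption probabilities (all in [0, 1])."""

    p_boundary_truncation: float = 0.0
    p_type_error: float = 0.0
    p_question: float = 0.0
    p_spurious_relation: float = 0.0
    p_passive_swap: float = 0.0
    p_negation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_boundary_truncation",
            "p_type_error",
            "p_question",
            "p_spurious_relation",
            "p_passive_swap",
            "p_negation",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass
class GoldBundle:
    """Gold documents, mentions and triples plus sentence-kind bookkeeping."""

    documents: List[TaggedDocument]
    gold_mentions: List[EntityMention]
    gold_triples: List[PredicationTriple]
    # (doc_id, sentence_index) → "relational" | "cooccurrence" | "negation"
    sentence_kinds: Dict[Tuple[str, int], str]
    config: GenConfig


@dataclass
class CorruptedBundle:
    """Simulated extractor output derived from a gold bundle."""

    triples: List[PredicationTriple]
    verifier_mentions: List[EntityMention]
    bookkeeping: Dict[str, list]
    noise: NoiseConfig


def _entity_tokens(surface: str) -> List[str]:
    return surface.split(" ")


def gen_gold(config: GenConfig) -> GoldBundle:
    """Deterministically generate a gold corpus.

    Every sentence carries exactly two entity mentions; relational
    sentences additionally assert one gold triple with a relation drawn
    from the schema whitelist.  All mentions satisfy the substring/offset
    invariants by construction.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = list(config.lexicon)
    if config.concepts is not None:
        wanted = set(config.concepts)
        missing = wanted - {e.concept for e in lexicon}
        if missing:
            raise ValueError(f"no lexicon surface forms for concepts {sorted(missing)}")
        lexicon = [e for e in lexicon if e.concept in wanted]
    if not lexicon:
        raise ValueError("empty lexicon")
    relations = sorted(config.schema.relations)
    verifier_ok = config.schema.verifier_concepts

    documents: List[TaggedDocument] = []
    mentions: List[EntityMention] = []
    triples: List[PredicationTriple] = []
    kinds: Dict[Tuple[str, int], str] = {}
    kind_names = ("relational", "cooccurrence", "negation")
    weights = np.asarray(config.kind_weights, dtype=float)
    weights = weights / weights.sum()

    for d in range(config.n_docs):
        doc_id = f"SYN{d:04d}"
        source = _SOURCES_CYCLE[d % len(_SOURCES_CYCLE)]
        sents: List[List[str]] = []
        labels: List[List[str]] = []
        offsets: List[List[Tuple[int, int]]] = []
        for s in range(config.sentences_per_doc):
            kind = kind_names[int(rng.choice(3, p=weights))]
            if kind == "relational":
                template = _RELATIONAL_TEMPLATES[int(rng.integers(len(_RELATIONAL_TEMPLATES)))]
            elif kind == "cooccurrence":
                template = _COOCCURRENCE_TEMPLATES[int(rng.integers(len(_COOCCURRENCE_TEMPLATES)))]
            else:
                template = _NEGATION_TEMPLATES[int(rng.integers(len(_NEGATION_TEMPLATES)))]
            i1, i2 = rng.choice(len(lexicon), size=2, replace=False)
            ents = [lexicon[int(i1)], lexicon[int(i2)]]
            surfaces = [
                e.surfaces[int(rng.integers(len(e.surfaces)))] for e in ents
            ]
            toks: List[str] = []
            labs: List[str] = []
            offs: List[Tuple[int, int]] = []
            span_bounds: List[Tuple[int, int]] = []  # char spans of the 2 entities
            pos = 0
            slot = 0
            for item in template:
                if item == "~":
                    ent_toks = _entity_tokens(surfaces[slot])
                    start_char = pos
                    for k, tok in enumerate(ent_toks):
                        toks.append(tok)
                        labs.append(("B-" if k == 0 else "I-") + ents[slot].concept)
                        offs.append((pos, pos + len(tok) - 1))
                        pos += len(tok) + 1
                    span_bounds.append((start_char, pos - 2))
                    slot += 1
                else:
                    toks.append(item)
                    labs.append("O")
                    offs.append((pos, pos + len(item) - 1))
                    pos += len(item) + 1
            sents.append(toks)
            labels.append(labs)
            offsets.append(offs)
            text = " ".join(toks)
            record = SentenceRecord(doc_id=doc_id, source=source, text=text, index=s)
            kinds[(doc_id, s)] = kind
            pair = []
            for (a, b), ent, surface in zip(span_bounds, ents, surfaces):
                m = EntityMention(
                    text_name=surface,
                    standard_name=ent.standard_name,
                    entity_id=ent.entity_id,
                    entity_type=ent.concept,
                    start_index=a,
                    end_index=b,
                    sentence=record,
                )
                mentions.append(m)
                pair.append(m)
            if kind == "relational":
                relation = relations[int(rng.integers(len(relations)))]
                triples.append(
                    PredicationTriple(
                        subject=pair[0],
                        relation=relation,
                        object=pair[1],
                        extractor="synthetic_gold",
                    )
                )
        doc = TaggedDocument(doc_id, sents, labels, offsets, source=source)
        doc.validate()
        documents.append(doc)
    _ = verifier_ok  # verifier scoping happens at corruption time
    return GoldBundle(documents, mentions, triples, kinds, config)


# --------------------------------------------------------------------------
# corruption

_QUESTION_PREFIX = "Is it true that "


def _shift_mention(m: EntityMention, new_sentence: SentenceRecord, delta: int) -> EntityMention:
    return replace(
        m,
        sentence=new_sentence,
        start_index=m.start_index + delta,
        end_index=m.end_index + delta,
    )


def _truncate(m: EntityMention) -> Optional[EntityMention]:
    """Drop the trailing token of a multiword mention; None if single-token."""
    if " " not in m.text_name:
        return None
    head = m.text_name.rsplit(" ", 1)[0]
    return replace(m, text_name=head, end_index=m.start_index + len(head) - 1)


def corrupt(gold: GoldBundle, noise: NoiseConfig) -> CorruptedBundle:
    """Simulate relation-extractor triples and verifier mentions from gold.

    Channels are applied independently per item at their configured rates
    using one uniform draw per candidate, so for a fixed seed the set of
    corrupted items grows monotonically with each probability.  With all
    probabilities zero the outputs equal the gold exactly (up to the
    ``extractor`` tag on triples).  The simulated verifier, like the NER
    system it stands in for, only emits mentions whose type is in the
    schema's verifier-concept inventory.
    """
    cfg = gold.config
    streams = np.random.SeedSequence(noise.seed).spawn(6)
    rng_question, rng_trunc, rng_type, rng_spur, rng_pass, rng_neg = (
        np.random.default_rng(s) for s in streams
    )
    book: Dict[str, list] = {
        "question_sentences": [],
        "truncated_mentions": [],
        "type_errors": [],
        "spurious_triples": [],
        "swapped_triples": [],
        "negation_triples": [],
    }

    # sentence-level question rendering (relational sentences only: the
    # channel emulates inconclusive sentences that still yielded a triple)
    sentence_rewrite: Dict[Tuple[str, int], Tuple[SentenceRecord, int]] = {}
    relational_keys = sorted(
        k for k, kind in gold.sentence_kinds.items() if kind == "relational"
    )
    sentence_of: Dict[Tuple[str, int], SentenceRecord] = {}
    for m in gold.gold_mentions:
        sentence_of[(m.sentence.doc_id, m.sentence.index)] = m.sentence
    for key in relational_keys:
        u = rng_question.uniform()
        if u < noise.p_question:
            old = sentence_of[key]
            new = replace(old, text=_QUESTION_PREFIX + old.text + "?")
            sentence_rewrite[key] = (new, len(_QUESTION_PREFIX))
            book["question_sentences"].append(key)

    def final_mention(m: EntityMention) -> EntityMention:
        key = (m.sentence.doc_id, m.sentence.index)
        if key in sentence_rewrite:
            new_sentence, delta = sentence_rewrite[key]
            return _shift_mention(m, new_sentence, delta)
        return m

    # relation-extractor triples
    sim_triples: List[PredicationTriple] = []
    for t in gold.gold_triples:
        subj, obj = final_mention(t.subject), final_mention(t.object)
        u = rng_pass.uniform()
        if u < noise.p_passive_swap:
            subj, obj = obj, subj
            book["swapped_triples"].append(t.key())
        sim_triples.append(
            PredicationTriple(subject=subj, relation=t.relation, object=obj,
                              extractor="relation_extractor")
        )

    # spurious triples from co-occurrence sentences, affirmative triples
    # from negation sentences
    by_sentence: Dict[Tuple[str, int], List[EntityMention]] = {}
    for m in gold.gold_mentions:
        by_sentence.setdefault((m.sentence.doc_id, m.sentence.index), []).append(m)
    relations = sorted(cfg.schema.relations)
    for key in sorted(k for k, kind in gold.sentence_kinds.items() if kind == "cooccurrence"):
        u = rng_spur.uniform()
        if u < noise.p_spurious_relation:
            a, b = by_sentence[key][:2]
            t = PredicationTriple(
                subject=final_mention(a),
                relation="associated_with" if "associated_with" in cfg.schema.relations else relations[0],
                object=final_mention(b),
                extractor="relation_extractor",
            )
            sim_triples.append(t)
            book["spurious_triples"].append(t.key())
    for key in sorted(k for k, kind in gold.sentence_kinds.items() if kind == "negation"):
        # both draws happen unconditionally so that, at a fixed seed, the
        # emitted set grows monotonically with p_negation
        u = rng_neg.uniform()
        rel_draw = int(rng_neg.integers(len(relations)))
        if u < noise.p_negation:
            a, b = by_sentence[key][:2]
            rel = relations[rel_draw]
            t = PredicationTriple(
                subject=final_mention(a),
                relation=rel,
                object=final_mention(b),
                extractor="relation_extractor",
            )
            sim_triples.append(t)
            book["negation_triples"].append(t.key())

    # simulated verifier mentions
    verifier_ok = cfg.schema.verifier_concepts
    verifier_mentions: List[EntityMention] = []
    for m in gold.gold_mentions:
        # unconditional draws keep the corrupted set monotone in each rate
        u_trunc = rng_trunc.uniform()
        u_type = rng_type.uniform()
        type_draw = int(rng_type.integers(1 << 30))
        if m.entity_type not in verifier_ok:
            continue
        vm = final_mention(m)
        if u_trunc < noise.p_boundary_truncation:
            truncated = _truncate(vm)
            if truncated is not None:
                vm = truncated
                book["truncated_mentions"].append(
                    (vm.sentence.doc_id, vm.sentence.index, m.text_name, vm.text_name)
                )
        if u_type < noise.p_type_error:
            others = sorted(verifier_ok - {vm.entity_type})
            if others:
                wrong = others[type_draw % len(others)]
                book["type_errors"].append(
                    (vm.sentence.doc_id, vm.sentence.index, vm.text_name, wrong)
                )
                vm = replace(vm, entity_type=wrong)
        verifier_mentions.append(vm)

    return CorruptedBundle(sim_triples, verifier_mentions, book, noise)


def end_to_end_benchmark(
    gold: GoldBundle,
    corrupted: CorruptedBundle,
    policy: VerifierPolicy | None = None,
) -> Dict[str, float]:
    """Run the filter pipeline on corrupted output; score against gold.

    Returns a report with retained-triple precision and recall relative
    to the gold triples (matched on document, sentence, canonical subject,
    relation, canonical object — direction-sensitive), plus raw counts.
    """
    report = run_filter_pipeline(
        corrupted.triples,
        corrupted.verifier_mentions,
        schema=gold.config.schema,
        policy=policy,
    )
    gold_keys = {t.key() for t in gold.gold_triples}
    retained_keys = [t.key() for t in report.retained]
    tp = sum(1 for k in retained_keys if k in gold_keys)
    precision = tp / len(retained_keys) if retained_keys else 1.0
    recall = tp / len(gold_keys) if gold_keys else 1.0
    return {
        "n_gold": len(gold_keys),
        "n_extracted": len(corrupted.triples),
        "n_retained": len(retained_keys),
        "n_removed": len(report.removed),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
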