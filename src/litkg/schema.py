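"""Knowledge-graph schema: concept inventory and relation whitelist.

The default inventory has nine concepts (drug subsumes chemical) and a
seven-concept subset that the NER verifier can produce.  The relation
whitelist defaults to 22 labels drawn from the UMLS Semantic Network
relation vocabulary; real deployments override it from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Tuple

import yaml

__all__ = [
    "DEFAULT_CONCEPTS",
    "DEFAULT_VERIFIER_CONCEPTS",
    "DEFAULT_RELATIONS",
    "SchemaConfig",
    "load_schema",
]

DEFAULT_CONCEPTS: Tuple[str, ...] = (
    "drug",
    "DNA",
    "RNA",
    "gene",
    "protein",
    "cell",
    "disease",
    "phenotypic_abnormality",
    "therapeutic_technique",
)

# The verifier recognises multi-type entities "such as disease, drug,
# protein, gene, DNA, RNA and cell" — the two remaining concepts are outside
# its inventory and are handled by the type_scoped verification policy.
DEFAULT_VERIFIER_CONCEPTS: Tuple[str, ...] = (
    "disease",
    "drug",
    "protein",
    "gene",
    "DNA",
    "RNA",
    "cell",
)

# Placeholder 22-label whitelist (UMLS Semantic Network relation names);
# user-overridable via the schema config.
DEFAULT_RELATIONS: Tuple[str, ...] = (
    "associated_with",
    "causes",
    "treats",
    "predisposes",
    "prevents",
    "affects",
    "interacts_with",
    "part_of",
    "location_of",
    "disrupts",
    "augments",
    "inhibits",
    "stimulates",
    "coexists_with",
    "complicates",
    "diagnoses",
    "administered_to",
    "produces",
    "precedes",
    "converts_to",
    "manifestation_of",
    "method_of",
)


@dataclass(frozen=True)
class SchemaConfig:
    """Concept inventory, relation whitelist and verifier-concept subset."""

    concepts: FrozenSet[str] = field(
        default_factory=lambda: frozenset(DEFAULT_CONCEPTS)
    )
    relations: FrozenSet[str] = field(
        default_factory=lambda: frozenset(DEFAULT_RELATIONS)
    )
    verifier_concepts: FrozenSet[str] = field(
        default_factory=lambda: frozenset(DEFAULT_VERIFIER_CONCEPTS)
    )

    def __post_init__(self) -> None:
        if not self.relations:
            raise ValueError("relation whitelist must be non-empty")
        extra = self.verifier_concepts - self.concepts
        if extra:
            raise ValueError(
                f"verifier concepts not in concept inventory: {sorted(extra)}"
            )

    @classmethod
    def default(cls) -> "SchemaConfig":
        return cls()


def load_schema(path: str | Path | None = None) -> SchemaConfig:
    """Load a schema config from YAML (or JSON, a YAML subset).

    Recognised keys: ``concepts``, ``relations``, ``verifier_concepts``.
    Missing keys fall back to the defaults; an empty or absent file yields
    the default schema.  A verifier concept outside ``concepts`` is an error.
    """
    if path is None:
        return SchemaConfig.default()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"schema config {path} must be a mapping")
    unknown = set(raw) - {"concepts", "relations", "verifier_concepts"}
    if unknown:
        raise ValueError(f"unknown schema config keys: {sorted(unknown)}")
    concepts = frozenset(raw.get("concepts") or DEFAULT_CONCEPTS)
    relations = frozenset(raw.get("relations") or DEFAULT_RELATIONS)
    if "verifier_concepts" in raw and raw["verifier_concepts"]:
        verifier = frozenset(raw["verifier_concepts"])
    else:
        verifier = frozenset(DEFAULT_VERIFIER_CONCEPTS) & concepts
    return SchemaConfig(
        concepts=concepts, relations=relations, verifier_concepts=verifier
    )
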