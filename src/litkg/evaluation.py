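"""Quality evaluation: annotator agreement, sampling, error taxonomy, P/R/F.

Two annotation teams each mark a set of triples TRUE; agreement is the
Jaccard index of those sets.  For error analysis, disagreeing triples are
assigned one of six categories (entity recognition, entity disambiguation,
non-existent relation, inaccurate relation, passive relation, negation
relation) and a text genre; the report gives each category's share of all
errors and, within a category, each genre's share.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Set, Tuple, TypeVar

import pandas as pd

__all__ = [
    "DISAGREEMENT_CATEGORIES",
    "GENRES",
    "DisagreementRecord",
    "jaccard_agreement",
    "sample_triples",
    "disagreement_report",
    "precision_recall_f",
    "f_from_pr",
    "accuracy_proportion",
]

T = TypeVar("T")

DISAGREEMENT_CATEGORIES = (
    "entity_recognition",
    "entity_disambiguation",
    "nonexistent_relation",
    "inaccurate_relation",
    "passive_relation",
    "negation_relation",
)

GENRES = ("literature", "uptodate", "clinicaltrials", "semmeddb")


@dataclass(frozen=True)
class DisagreementRecord:
    """One annotator disagreement, categorized."""

    triple_id: str
    category: str
    genre: str

    def __post_init__(self) -> None:
        if self.category not in DISAGREEMENT_CATEGORIES:
            raise ValueError(f"unknown disagreement category {self.category!r}")
        if self.genre not in GENRES:
            raise ValueError(f"unknown text genre {self.genre!r}")


def jaccard_agreement(a: Set[str], b: Set[str]) -> float:
    """|A∩B| / |A∪B|.  Two empty sets agree vacuously → 1."""
    union = set(a) | set(b)
    if not union:
        return 1.0
    return len(set(a) & set(b)) / len(union)


def sample_triples(edges: Sequence[T], n: int, seed: int) -> List[T]:
    """Simple random sample of ``n`` items without replacement, seeded."""
    if n > len(edges):
        raise ValueError(f"cannot sample {n} from {len(edges)} triples")
    return random.Random(seed).sample(list(edges), n)


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _pct_trunc(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(int(frac * 100) / Decimal(100))


def disagreement_report(
    records: Sequence[DisagreementRecord], truncated: bool = False
) -> pd.DataFrame:
    """Per-category error shares, with per-genre shares within category.

    One row per category: ``count``, ``overall_pct`` (share of all
    records, half-up to 2 decimals), and per-genre ``<genre>_count`` /
    ``<genre>_pct`` (share within the category).  ``truncated=True`` adds
    a ``overall_pct_trunc`` audit column (some published tables truncate
    rather than round).
    """
    if not records:
        raise ValueError("disagreement_report requires at least one record")
    total = len(records)
    rows = []
    for cat in DISAGREEMENT_CATEGORIES:
        in_cat = [r for r in records if r.category == cat]
        row: Dict[str, object] = {
            "category": cat,
            "count": len(in_cat),
            "overall_pct": _pct(len(in_cat), total),
        }
        if truncated:
            row["overall_pct_trunc"] = _pct_trunc(len(in_cat), total)
        for genre in GENRES:
            k = sum(1 for r in in_cat if r.genre == genre)
            row[f"{genre}_count"] = k
            row[f"{genre}_pct"] = _pct(k, len(in_cat))
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def precision_recall_f(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Precision, recall and F1 (as percentages) from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return p, r, f_from_pr(p, r)


def f_from_pr(p: float, r: float) -> float:
    """Harmonic mean F = 2PR/(P+R); 0 when P + R = 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def accuracy_proportion(n_correct: int, n_sampled: int) -> float:
    """Marked-correct / sampled, as a percentage (manual-audit accuracy)."""
    if n_sampled <= 0:
        raise ValueError("sample size must be positive")
    if not 0 <= n_correct <= n_sampled:
        raise ValueError("correct count outside [0, sample size]")
    return 100.0 * n_correct / n_sampled
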