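"""Evidence scoring: mapping, strength, and composite evidence scores.

Each classified evidence item gets three numbers:

* mapping score — the product of the four harmonization similarities
  (query -> ontology -> evidence entity, on both the subject and the object
  side).  With typical per-step similarities in [0.85, 0.92] the composite
  lies in [0.522, 0.717]; exact-match chains score 1.
* strength score — magnitude of the evidence itself.  For literature triples
  it is ``1 + log10(n)`` for ``n`` source articles: a single-article triple
  scores 1, a 10-article triple 2, a 20-article triple ~2.3.  For
  associations it is ``|effect / SE| / z(pi)`` where ``z(pi)`` is the
  two-sided standard-normal critical value at the significance threshold
  ``pi``; the score is exactly 1 at the significance boundary, above 1 for
  items that pass it, below 1 for insufficient items.
* evidence score — the product of the two, summed within each
  (evidence group, evidence type) cell to give the aggregates used for
  prioritization.

All three are isolated pure functions so alternative formulations can be
swapped in without touching the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import norm

from .engine import ClassifiedEvidence, EvidenceGroup, EvidenceType

__all__ = [
    "ScoredEvidence",
    "AggregateScores",
    "mapping_score",
    "strength_score_triple",
    "strength_score_assoc",
    "evidence_score",
    "score_evidence",
    "aggregate_scores",
    "normal_critical_value",
    "two_sided_p",
]


class ScoreContractError(ValueError):
    """An input violates a scoring precondition."""


def normal_critical_value(p_threshold: float) -> float:
    """Two-sided standard-normal critical value z(pi)."""
    if not (0.0 < p_threshold < 1.0):
        raise ScoreContractError(f"p threshold must be in (0, 1), got {p_threshold}")
    return float(norm.isf(p_threshold / 2.0))


def two_sided_p(effect_size: float, standard_error: float) -> float:
    """Two-sided normal-test P-value of an (effect, SE) pair."""
    if standard_error <= 0:
        raise ScoreContractError("standard_error must be > 0")
    return float(2.0 * norm.sf(abs(effect_size / standard_error)))


def _check_similarity(x: float) -> None:
    if not (0.0 < x <= 1.0):
        raise ScoreContractError(f"chain similarity must be in (0, 1], got {x}")


def mapping_score(
    subject_chain_sims: Sequence[float], object_chain_sims: Sequence[float]
) -> float:
    """Product of the per-step similarities of both harmonization chains."""
    if len(subject_chain_sims) != 2 or len(object_chain_sims) != 2:
        raise ScoreContractError(
            "each chain must have exactly two steps (query->ontology, ontology->evidence)"
        )
    out = 1.0
    for sim in (*subject_chain_sims, *object_chain_sims):
        _check_similarity(sim)
        out *= sim
    return out


def strength_score_triple(n_literature: int) -> float:
    """``1 + log10(n)`` source articles; 1 for a single-article triple."""
    if n_literature < 1:
        raise ScoreContractError(f"n_literature must be >= 1, got {n_literature}")
    return 1.0 + math.log10(n_literature)


def strength_score_assoc(
    effect_size: float, standard_error: float, p_threshold: float
) -> float:
    """Standardized effect relative to the significance boundary at ``p_threshold``."""
    if standard_error <= 0:
        raise ScoreContractError(f"standard_error must be > 0, got {standard_error}")
    return abs(effect_size / standard_error) / normal_critical_value(p_threshold)


def evidence_score(mapping: float, strength: float) -> float:
    return mapping * strength


@dataclass(frozen=True)
class ScoredEvidence:
    classified: ClassifiedEvidence
    mapping_score: float
    strength_score: float
    evidence_score: float


def score_evidence(
    items: Iterable[ClassifiedEvidence], p_threshold: float
) -> list:
    """Score every classified item; returns :class:`ScoredEvidence` in input order."""
    out = []
    for item in items:
        m = mapping_score(item.subject_chain, item.object_chain)
        if item.group is EvidenceGroup.TRIPLE_LIT:
            s = strength_score_triple(len(item.item.literature_ids))
        else:
            s = strength_score_assoc(
                item.item.effect_size, item.item.standard_error, p_threshold
            )
        out.append(
            ScoredEvidence(
                classified=item,
                mapping_score=m,
                strength_score=s,
                evidence_score=evidence_score(m, s),
            )
        )
    return out


@dataclass(frozen=True)
class AggregateScores:
    """Per-(group, type) item counts and summed evidence scores."""

    cells: tuple  # ((group, type, count, total), ...) in stable enum order

    def count(self, group: EvidenceGroup, etype: EvidenceType) -> int:
        for g, t, c, _ in self.cells:
            if g is group and t is etype:
                return c
        return 0

    def total(self, group: EvidenceGroup, etype: EvidenceType) -> float:
        for g, t, _, s in self.cells:
            if g is group and t is etype:
                return s
        return 0.0


def aggregate_scores(items: Iterable[ScoredEvidence]) -> AggregateScores:
    """Sum evidence scores and count items within each (group, type) cell."""
    counts: dict[tuple, int] = {}
    totals: dict[tuple, float] = {}
    for g in EvidenceGroup:
        for t in EvidenceType:
            counts[(g, t)] = 0
            totals[(g, t)] = 0.0
    for item in items:
        key = (item.classified.group, item.classified.type)
        counts[key] += 1
        totals[key] += item.evidence_score
    cells = tuple(
        (g, t, counts[(g, t)], totals[(g, t)])
        for g in EvidenceGroup
        for t in EvidenceType
    )
    return AggregateScores(cells=cells)
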