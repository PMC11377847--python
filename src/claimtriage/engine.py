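"""Evidence retrieval and classification for a harmonized claim.

Claims split into two predicate groups — directional (AFFECTS, CAUSES,
PRODUCES, TREATS) and non-directional (ASSOCIATED_WITH, COEXISTS_WITH,
INTERACTS_WITH) — and every retrieved evidence item is assigned exactly one
evidence type by a fixed rule table:

========================  ============  =========  ============  ==========
                          supporting    reversal   insufficient  additional
========================  ============  =========  ============  ==========
directional, triple       S-P->O        O-P->S     n/a           n/a
directional, association  S->O, p < pi  O->S,      either way,   non-dir.
                                        p < pi     p >= pi       record
non-directional, triple   S-P-O         n/a        n/a           n/a
non-dir., association     S-P-O,        n/a        S-P-O,        n/a
                          p < pi                   p >= pi
========================  ============  =========  ============  ==========

where S and O stand for the evidence entities harmonized to the claim's
subject and object sides.  Reversal evidence supports the direction-swapped
claim; insufficient association evidence exists but fails the P-value
threshold ``pi``; additional evidence is non-directional context for a
directional claim (no P-value condition).  Association records whose two
traits harmonized to the *same* side only (self-pairs, source == target) are
excluded and logged.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pydantic import BaseModel, Field

from .harmonization import HarmonizationConfig, HarmonizationResult, harmonize_claim
from .kg import (
    AssociationType,
    ClaimTriple,
    DIRECTIONAL_PREDICATES,
    KnowledgeGraph,
    Predicate,
    Taxonomy,
    coerce_predicate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredicateGroup",
    "EvidenceGroup",
    "EvidenceType",
    "Orientation",
    "ClassifiedEvidence",
    "EvidenceConfig",
    "predicate_group",
    "classify_triple_evidence",
    "classify_association_evidence",
    "run_query",
]


class PredicateGroup(str, enum.Enum):
    DIRECTIONAL = "DIRECTIONAL"
    NON_DIRECTIONAL = "NON_DIRECTIONAL"


class EvidenceGroup(str, enum.Enum):
    TRIPLE_LIT = "TRIPLE_LIT"
    ASSOC = "ASSOC"


class EvidenceType(str, enum.Enum):
    SUPPORTING = "SUPPORTING"
    REVERSAL = "REVERSAL"
    INSUFFICIENT = "INSUFFICIENT"
    ADDITIONAL = "ADDITIONAL"


class Orientation(str, enum.Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


def predicate_group(predicate) -> PredicateGroup:
    """The fixed directional / non-directional partition of the predicates."""
    predicate = coerce_predicate(predicate)
    if predicate in DIRECTIONAL_PREDICATES:
        return PredicateGroup.DIRECTIONAL
    return PredicateGroup.NON_DIRECTIONAL


@dataclass(frozen=True)
class ClassifiedEvidence:
    """One evidence record with its assigned type and harmonization chains.

    ``subject_chain`` / ``object_chain`` are the (query->ontology,
    ontology->evidence) similarity pairs through which the claim's subject
    and object sides reached this record's entities.
    """

    item: object  # TripleEvidenceRecord | AssociationRecord
    group: EvidenceGroup
    type: EvidenceType
    orientation: Orientation
    subject_chain: tuple
    object_chain: tuple

    @property
    def key(self) -> tuple:
        return self.item.key


class EvidenceConfig(BaseModel):
    """Classification thresholds and per-group association-type toggles."""

    p_threshold: float = Field(default=1e-3, gt=0.0, lt=1.0)
    directional_assoc_types: frozenset = frozenset(AssociationType)
    non_directional_assoc_types: frozenset = frozenset(AssociationType)
    additional_requires_p: bool = False


# -- triple and literature group ------------------------------------------


def classify_triple_evidence(
    harm: HarmonizationResult, claim: ClaimTriple, kg: KnowledgeGraph
) -> list:
    """Classify literature triples linking the two harmonized sides.

    Directional claims yield SUPPORTING (same orientation) and REVERSAL
    (swapped orientation) items; non-directional claims match in either
    orientation and yield SUPPORTING only.  A record that matches both
    orientations (an entity harmonized to both sides) is counted once, as
    SUPPORTING.
    """
    subj = harm.subject.entity_ids(Taxonomy.LIT_TERM)
    obj = harm.object.entity_ids(Taxonomy.LIT_TERM)
    group = predicate_group(claim.predicate)
    out: dict[tuple, ClassifiedEvidence] = {}

    for rec in kg.triples_matching(subj, claim.predicate, obj):
        out[rec.key] = ClassifiedEvidence(
            item=rec,
            group=EvidenceGroup.TRIPLE_LIT,
            type=EvidenceType.SUPPORTING,
            orientation=Orientation.FORWARD,
            subject_chain=harm.subject.chain(Taxonomy.LIT_TERM, rec.subject_id),
            object_chain=harm.object.chain(Taxonomy.LIT_TERM, rec.object_id),
        )
    for rec in kg.triples_matching(obj, claim.predicate, subj):
        if rec.key in out:
            continue  # already supporting via the forward orientation
        swapped_type = (
            EvidenceType.REVERSAL
            if group is PredicateGroup.DIRECTIONAL
            else EvidenceType.SUPPORTING
        )
        out[rec.key] = ClassifiedEvidence(
            item=rec,
            group=EvidenceGroup.TRIPLE_LIT,
            type=swapped_type,
            orientation=(
                Orientation.REVERSE
                if group is PredicateGroup.DIRECTIONAL
                else Orientation.FORWARD
            ),
            # the claim's subject side reached this record's *object* entity
            subject_chain=harm.subject.chain(Taxonomy.LIT_TERM, rec.object_id),
            object_chain=harm.object.chain(Taxonomy.LIT_TERM, rec.subject_id),
        )
    return sorted(out.values(), key=lambda c: c.key)


# -- association group -----------------------------------------------------


def classify_association_evidence(
    harm: HarmonizationResult,
    claim: ClaimTriple,
    kg: KnowledgeGraph,
    cfg: EvidenceConfig | None = None,
) -> list:
    """Classify trait-pair association records per the rule table."""
    cfg = cfg or EvidenceConfig()
    pi = cfg.p_threshold
    subj = harm.subject.entity_ids(Taxonomy.TRAIT)
    obj = harm.object.entity_ids(Taxonomy.TRAIT)
    group = predicate_group(claim.predicate)
    enabled = (
        cfg.directional_assoc_types
        if group is PredicateGroup.DIRECTIONAL
        else cfg.non_directional_assoc_types
    )
    out: dict[tuple, ClassifiedEvidence] = {}

    def chains(source_side: str, rec):
        """Chains given which claim side the record's source trait matched."""
        if source_side == "subject":
            return (
                harm.subject.chain(Taxonomy.TRAIT, rec.source_trait_id),
                harm.object.chain(Taxonomy.TRAIT, rec.target_trait_id),
            )
        return (
            harm.subject.chain(Taxonomy.TRAIT, rec.target_trait_id),
            harm.object.chain(Taxonomy.TRAIT, rec.source_trait_id),
        )

    def emit(rec, etype, orientation, source_side):
        if rec.key in out:
            return
        if rec.source_trait_id == rec.target_trait_id:
            logger.info("excluding self-pair association record %s", rec.key)
            return
        s_chain, o_chain = chains(source_side, rec)
        out[rec.key] = ClassifiedEvidence(
            item=rec,
            group=EvidenceGroup.ASSOC,
            type=etype,
            orientation=orientation,
            subject_chain=s_chain,
            object_chain=o_chain,
        )

    records = kg.associations_between(subj | obj, subj | obj, enabled)
    if group is PredicateGroup.DIRECTIONAL:
        for rec in records:
            forward = rec.source_trait_id in subj and rec.target_trait_id in obj
            reverse = rec.source_trait_id in obj and rec.target_trait_id in subj
            if not (forward or reverse):
                continue
            if rec.directional:
                # forward takes precedence if a trait harmonized to both sides
                orientation = Orientation.FORWARD if forward else Orientation.REVERSE
                source_side = "subject" if forward else "object"
                if rec.p_value < pi:
                    etype = (
                        EvidenceType.SUPPORTING
                        if orientation is Orientation.FORWARD
                        else EvidenceType.REVERSAL
                    )
                else:
                    etype = EvidenceType.INSUFFICIENT
                emit(rec, etype, orientation, source_side)
            else:
                if cfg.additional_requires_p and rec.p_value >= pi:
                    continue
                source_side = "subject" if forward else "object"
                emit(rec, EvidenceType.ADDITIONAL, Orientation.FORWARD, source_side)
    else:
        for rec in records:
            forward = rec.source_trait_id in subj and rec.target_trait_id in obj
            reverse = rec.source_trait_id in obj and rec.target_trait_id in subj
            if not (forward or reverse):
                continue
            source_side = "subject" if forward else "object"
            etype = (
                EvidenceType.SUPPORTING if rec.p_value < pi else EvidenceType.INSUFFICIENT
            )
            emit(rec, etype, Orientation.FORWARD, source_side)
    return sorted(out.values(), key=lambda c: c.key)


# -- orchestration ---------------------------------------------------------


def run_query(
    claim: ClaimTriple,
    kg: KnowledgeGraph,
    harm_cfg: HarmonizationConfig | None = None,
    ev_cfg: EvidenceConfig | None = None,
):
    """End-to-end query: harmonize, classify both groups, score, report.

    Fully deterministic for a fixed graph and configuration.  Returns an
    :class:`~claimtriage.report.EvidenceReport`.
    """
    from . import report as report_mod
    from . import scoring

    coerce_predicate(claim.predicate)  # fail fast before any retrieval
    harm_cfg = harm_cfg or HarmonizationConfig()
    ev_cfg = ev_cfg or EvidenceConfig()

    harm = harmonize_claim(claim, kg, harm_cfg)
    classified = classify_triple_evidence(harm, claim, kg) + classify_association_evidence(
        harm, claim, kg, ev_cfg
    )
    scored = scoring.score_evidence(classified, ev_cfg.p_threshold)
    aggregates = scoring.aggregate_scores(scored)
    logger.info(
        "claim (%s %s %s): %d classified items",
        claim.subject_term,
        claim.predicate.value,
        claim.object_term,
        len(scored),
    )
    return report_mod.build_report(claim, harm, scored, aggregates, harm_cfg, ev_cfg)
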