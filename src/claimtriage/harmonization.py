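"""Two-stage entity harmonization.

Stage 1 maps each free-text claim term to candidate ontology terms by
embedding similarity, annotates every candidate with an information-content
score (how concrete the term is in the ontology) and an identity score (an
inferred distance between the query term and the candidate; lower is
closer), and selects the candidates that pass both thresholds.  Stage 2 maps
each selected ontology term to evidence entities — literature-vocabulary
terms and GWAS traits — again by embedding similarity.

The per-step similarities of each chain (query -> ontology -> evidence
entity) are retained: the scoring layer multiplies them into the mapping
score of every evidence item reached through that chain.

Scores
------
* information content: ``IC(t) = 1 - log(|descendants(t)| + 1) / log(N)``
  for an ontology of ``N`` terms; leaves score 1, a root covering the whole
  ontology scores 0.
* identity score (default estimator): ``1 - cosine(encode(query),
  encode(label))`` clamped to [0, 1].  Alternative distance models (e.g. a
  trained cross-encoder) can be registered and selected by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

from pydantic import BaseModel, Field, model_validator

from . import encoder as enc
from .kg import ClaimTriple, Entity, GraphLookupError, KnowledgeGraph, Taxonomy

__all__ = [
    "OntologyCandidate",
    "EvidenceEntityMapping",
    "SideHarmonization",
    "HarmonizationResult",
    "HarmonizationConfig",
    "retrieve_ontology_candidates",
    "information_content",
    "identity_score",
    "select_candidates",
    "map_to_evidence_entities",
    "harmonize_claim",
    "register_identity_estimator",
]


class HarmonizationConfig(BaseModel):
    """Thresholds of the two stages.

    ``min_evidence_similarity`` is calibrated to the active encoder: the
    trigram fallback scores near-identical labels (one character edit per
    word) around 0.65-0.75, whereas trained sentence encoders put such pairs
    at 0.85+, so deployments with a transformer encoder should raise it.
    """

    k_candidates: int = Field(default=10, ge=1)
    min_candidate_similarity: float = Field(default=0.70, ge=0.0, le=1.0)
    identity_threshold: float = Field(default=0.20, ge=0.0, le=1.0)
    ic_range: tuple = (0.3, 1.0)
    min_evidence_similarity: float = Field(default=0.60, ge=0.0, le=1.0)
    k_evidence: int = Field(default=5, ge=1)
    encoder: str = "fallback"
    identity_estimator: str = "embedding"
    use_synonyms: bool = True
    allow_fallback_selection: bool = True

    @model_validator(mode="after")
    def _check_ic_range(self):
        lo, hi = self.ic_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ic_range must satisfy 0 <= low <= high <= 1")
        return self


@dataclass
class OntologyCandidate:
    """An ontology term retrieved as a stage-1 candidate for a claim term."""

    term_id: str
    label: str
    similarity: float
    ic_score: float
    identity_score: float
    selected: bool = False


@dataclass(frozen=True)
class EvidenceEntityMapping:
    """A stage-2 chain step from a selected ontology term to an evidence entity.

    ``query_similarity`` is the stage-1 similarity (claim term -> ontology
    term); ``similarity`` is the stage-2 similarity (ontology label ->
    evidence label).  Their product ranks competing chains to the same
    evidence entity.
    """

    ontology_term_id: str
    entity: Entity
    similarity: float
    query_similarity: float

    @property
    def chain(self) -> tuple:
        return (self.query_similarity, self.similarity)


@dataclass
class SideHarmonization:
    """Full harmonization state for one side (subject or object) of a claim."""

    query_term: str
    candidates: list = field(default_factory=list)
    fallback_used: bool = False
    lit_mappings: list = field(default_factory=list)
    trait_mappings: list = field(default_factory=list)

    @property
    def selected_terms(self) -> list:
        return [c for c in self.candidates if c.selected]

    @property
    def selected_term_ids(self) -> list:
        return [c.term_id for c in self.selected_terms]

    def mappings(self, taxonomy: Taxonomy) -> list:
        if taxonomy is Taxonomy.LIT_TERM:
            return self.lit_mappings
        if taxonomy is Taxonomy.TRAIT:
            return self.trait_mappings
        raise ValueError(f"no evidence mappings for taxonomy {taxonomy}")

    def entity_ids(self, taxonomy: Taxonomy) -> set:
        return {m.entity.id for m in self.mappings(taxonomy)}

    def chain(self, taxonomy: Taxonomy, entity_id: str) -> tuple:
        """(query->ontology, ontology->evidence) similarities for an entity."""
        for m in self.mappings(taxonomy):
            if m.entity.id == entity_id:
                return m.chain
        raise GraphLookupError(
            f"no {taxonomy.value} mapping for entity {entity_id!r} "
            f"on side {self.query_term!r}"
        )

    @property
    def is_empty(self) -> bool:
        return not (self.lit_mappings or self.trait_mappings)


@dataclass
class HarmonizationResult:
    subject: SideHarmonization
    object: SideHarmonization

    @property
    def has_mappings(self) -> bool:
        return not (self.subject.is_empty and self.object.is_empty)


# -- scores ----------------------------------------------------------------


def information_content(kg: KnowledgeGraph, term_id: str) -> float:
    """Concreteness of an ontology term: 1 for leaves, 0 for an all-covering root."""
    n = kg.n_ontology_terms
    if n < 2:
        raise ValueError("information content requires an ontology of >= 2 terms")
    d = len(kg.ontology_descendants(term_id))
    return 1.0 - math.log(d + 1) / math.log(n)


_IDENTITY_ESTIMATORS: dict = {}


def register_identity_estimator(name: str, fn: Callable) -> None:
    """Register a ``(query_text, candidate_label, encoder) -> distance`` model."""
    _IDENTITY_ESTIMATORS[name] = fn


def _embedding_identity(term: str, label: str, encoder) -> float:
    sim = enc.cosine(encoder.encode(term), encoder.encode(label))
    return min(1.0, max(0.0, 1.0 - sim))


register_identity_estimator("embedding", _embedding_identity)


def identity_score(
    term: str,
    candidate_term_id: str,
    kg: KnowledgeGraph,
    encoder=None,
    estimator: str = "embedding",
) -> float:
    """Inferred distance between a query term and an ontology candidate.

    Lower is closer; 0 for identical text under the default estimator.
    """
    label = kg.entity(Taxonomy.ONTOLOGY, candidate_term_id).label
    encoder = encoder or enc.get_encoder("fallback")
    return _IDENTITY_ESTIMATORS[estimator](term, label, encoder)


# -- stage 1 ---------------------------------------------------------------


def _best_similarity(query_vec, entity: Entity, encoder, use_synonyms: bool) -> float:
    labels = (entity.label,) + (entity.synonyms if use_synonyms else ())
    return max(enc.cosine(query_vec, encoder.encode(lbl)) for lbl in labels)


def retrieve_ontology_candidates(
    term: str,
    kg: KnowledgeGraph,
    cfg: HarmonizationConfig | None = None,
    encoder=None,
) -> list:
    """Top-k ontology candidates for a claim term, scored but unselected."""
    cfg = cfg or HarmonizationConfig()
    encoder = encoder or enc.get_encoder(cfg.encoder)
    query_vec = encoder.encode(term)
    scored = []
    for entity in kg.entities(Taxonomy.ONTOLOGY):
        sim = _best_similarity(query_vec, entity, encoder, cfg.use_synonyms)
        if sim >= cfg.min_candidate_similarity:
            scored.append((entity, sim))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    out = []
    for entity, sim in scored[: cfg.k_candidates]:
        out.append(
            OntologyCandidate(
                term_id=entity.id,
                label=entity.label,
                similarity=sim,
                ic_score=information_content(kg, entity.id),
                identity_score=identity_score(
                    term, entity.id, kg, encoder, cfg.identity_estimator
                ),
            )
        )
    return out


def select_candidates(
    candidates: list, cfg: HarmonizationConfig | None = None
) -> tuple:
    """Apply the selection rule; returns ``(candidates, fallback_used)``.

    A candidate is selected iff its identity score is at or below the
    identity threshold and its IC score lies inside ``ic_range``.  When no
    candidate qualifies and fallback selection is enabled, the single
    highest-similarity candidate is selected and flagged, so a permissive
    query still has an anchor term.  Order is preserved.
    """
    cfg = cfg or HarmonizationConfig()
    lo, hi = cfg.ic_range
    out = [
        replace(
            c,
            selected=(c.identity_score <= cfg.identity_threshold and lo <= c.ic_score <= hi),
        )
        for c in candidates
    ]
    fallback_used = False
    if out and not any(c.selected for c in out) and cfg.allow_fallback_selection:
        best = min(range(len(out)), key=lambda i: (-out[i].similarity, out[i].term_id))
        out[best] = replace(out[best], selected=True)
        fallback_used = True
    return out, fallback_used


# -- stage 2 ---------------------------------------------------------------


def map_to_evidence_entities(
    selected_terms: Iterable[OntologyCandidate],
    taxonomy: Taxonomy,
    kg: KnowledgeGraph,
    cfg: HarmonizationConfig | None = None,
    encoder=None,
) -> list:
    """Map selected ontology terms to evidence entities of one taxonomy.

    For each ontology term the top ``k_evidence`` entities with similarity at
    or above ``min_evidence_similarity`` are kept.  When two ontology terms
    reach the same evidence entity, the chain with the larger similarity
    product wins.
    """
    cfg = cfg or HarmonizationConfig()
    encoder = encoder or enc.get_encoder(cfg.encoder)
    catalog = kg.entities(taxonomy)
    best: dict[str, EvidenceEntityMapping] = {}
    for cand in selected_terms:
        onto_vec = encoder.encode(cand.label)
        scored = []
        for entity in catalog:
            sim = _best_similarity(onto_vec, entity, encoder, cfg.use_synonyms)
            if sim >= cfg.min_evidence_similarity:
                scored.append((entity, sim))
        scored.sort(key=lambda t: (-t[1], t[0].id))
        for entity, sim in scored[: cfg.k_evidence]:
            mapping = EvidenceEntityMapping(
                ontology_term_id=cand.term_id,
                entity=entity,
                similarity=sim,
                query_similarity=cand.similarity,
            )
            prev = best.get(entity.id)
            if prev is None or _chain_weight(mapping) > _chain_weight(prev):
                best[entity.id] = mapping
    return sorted(best.values(), key=lambda m: m.entity.id)


def _chain_weight(m: EvidenceEntityMapping) -> float:
    return m.query_similarity * m.similarity


# -- full chain ------------------------------------------------------------


def harmonize_side(
    term: str, kg: KnowledgeGraph, cfg: HarmonizationConfig, encoder
) -> SideHarmonization:
    candidates = retrieve_ontology_candidates(term, kg, cfg, encoder)
    candidates, fallback_used = select_candidates(candidates, cfg)
    selected = [c for c in candidates if c.selected]
    return SideHarmonization(
        query_term=term,
        candidates=candidates,
        fallback_used=fallback_used,
        lit_mappings=map_to_evidence_entities(selected, Taxonomy.LIT_TERM, kg, cfg, encoder),
        trait_mappings=map_to_evidence_entities(selected, Taxonomy.TRAIT, kg, cfg, encoder),
    )


def harmonize_claim(
    claim: ClaimTriple,
    kg: KnowledgeGraph,
    cfg: HarmonizationConfig | None = None,
) -> HarmonizationResult:
    """Run both harmonization stages independently for subject and object."""
    cfg = cfg or HarmonizationConfig()
    encoder = enc.get_encoder(cfg.encoder)
    return HarmonizationResult(
        subject=harmonize_side(claim.subject_term, kg, cfg, encoder),
        object=harmonize_side(claim.object_term, kg, cfg, encoder),
    )
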