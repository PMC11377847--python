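"""Shared fixtures: hand-built miniature graphs and generator conditions."""

from __future__ import annotations

import numpy as np
import pytest

from claimtriage.kg import (
    AssociationRecord,
    AssociationType,
    Entity,
    KnowledgeGraph,
    LiteratureRecord,
    OntologyEdge,
    Predicate,
    Taxonomy,
    TripleEvidenceRecord,
)
from claimtriage.synthetic import GeneratorConfig, PlantedClaim, synthesize_labels


def ent(taxonomy, eid, label, **kw):
    return Entity(Taxonomy[taxonomy], eid, label, **kw)


@pytest.fixture
def glucose_kg():
    """A miniature graph around the claim "Glucose TREATS Diabetes".

    The ontology holds a "glucose" term and a small diabetes family; the
    literature vocabulary holds UMLS-style copies; the trait taxonomy holds
    two glucose GWAS variants and a diabetes trait; one literature triple
    and two associations link the two sides.
    """
    entities = [
        ent("ONTOLOGY", "EFO:0000001", "experimental factor"),
        ent("ONTOLOGY", "CHEBI:17234", "glucose"),
        ent("ONTOLOGY", "EFO:0000400", "diabetes mellitus"),
        ent("ONTOLOGY", "EFO:0004593", "monogenic diabetes"),
        ent("ONTOLOGY", "EFO:0009605", "maternal diabetes"),
        ent("ONTOLOGY", "EFO:0003767", "inflammatory bowel disease"),
        ent("LIT_TERM", "C0017725", "glucose", semantic_types=frozenset({"bacs"})),
        ent("LIT_TERM", "C0011849", "diabetes mellitus", semantic_types=frozenset({"dsyn"})),
        ent("LIT_TERM", "C0021390", "inflammatory bowel disease",
            semantic_types=frozenset({"dsyn"})),
        ent("TRAIT", "ukb-d-30740_irnt", "glucose (irnt)"),
        ent("TRAIT", "ukb-d-30740_raw", "glucose (raw)"),
        ent("TRAIT", "ukb-b-10753", "diabetes mellitus"),
    ]
    edges = [
        OntologyEdge("CHEBI:17234", "EFO:0000001"),
        OntologyEdge("EFO:0000400", "EFO:0000001"),
        OntologyEdge("EFO:0004593", "EFO:0000400"),
        OntologyEdge("EFO:0009605", "EFO:0000400"),
        OntologyEdge("EFO:0003767", "EFO:0000001"),
    ]
    literature = [
        LiteratureRecord("PMID:1", "glucose infusion in diabetic ketoacidosis"),
        LiteratureRecord("PMID:2", "glycaemic control trial"),
    ]
    triples = [
        TripleEvidenceRecord("C0017725", Predicate.TREATS, "C0011849",
                             ("PMID:1", "PMID:2")),
    ]
    associations = [
        AssociationRecord("ukb-d-30740_irnt", "ukb-b-10753",
                          AssociationType.MR_EVE_MR, 0.30, 0.05, 2e-9),
        AssociationRecord("ukb-d-30740_raw", "ukb-b-10753",
                          AssociationType.GEN_COR, 0.15, 0.08, 0.06),
    ]
    return KnowledgeGraph(entities, edges, triples, associations, literature)


def make_generator_config(seed, noise, n_claims=10):
    """The standard planted-claim study condition: synthesized three-word
    labels, all seven predicates, a mixed evidence composition per claim.
    """
    predicates = [
        "CAUSES", "TREATS", "AFFECTS", "PRODUCES",
        "ASSOCIATED_WITH", "COEXISTS_WITH", "INTERACTS_WITH",
        "CAUSES", "TREATS", "AFFECTS",
    ][:n_claims]
    label_rng = np.random.default_rng(seed + 10_000)
    labels = synthesize_labels(2 * n_claims, label_rng)
    plants = []
    for i, pred in enumerate(predicates):
        counts = dict(
            n_supporting_triples=2,
            n_reversal_triples=1,
            n_supporting_assocs=2,
            n_reversal_assocs=1,
            n_insufficient_assocs=2,
            n_additional_assocs=2,
        )
        if pred in ("ASSOCIATED_WITH", "COEXISTS_WITH", "INTERACTS_WITH"):
            counts.update(n_reversal_triples=0, n_reversal_assocs=0,
                          n_additional_assocs=0)
        plants.append(
            PlantedClaim(
                subject_label=labels[2 * i],
                predicate=pred,
                object_label=labels[2 * i + 1],
                **counts,
            )
        )
    return GeneratorConfig(
        seed=seed,
        label_noise_level=noise,
        n_ontology_terms=40,
        n_lit_terms=50,
        n_traits=40,
        n_background_triples=60,
        n_background_assocs=80,
        planted_claims=plants,
    )


OBO_FIXTURE = """format-version: 1.2
ontology: demo

[Term]
id: DEMO:0000001
name: phenotype

[Term]
id: DEMO:0000002
name: metabolic disease
is_a: DEMO:0000001 ! phenotype

[Term]
id: DEMO:0000003
name: diabetes mellitus
synonym: "diabetes" EXACT []
is_a: DEMO:0000002 ! metabolic disease

[Term]
id: DEMO:0000004
name: type II diabetes
is_a: DEMO:0000003 ! diabetes mellitus

[Term]
id: DEMO:0000005
name: cardiovascular disease
is_a: DEMO:0000001 ! phenotype

[Term]
id: DEMO:0000006
name: heart failure
is_a: DEMO:0000005 ! cardiovascular disease

[Term]
id: DEMO:0000007
name: hypertension
is_a: DEMO:0000005 ! cardiovascular disease

[Term]
id: DEMO:0000008
name: obesity
is_a: DEMO:0000002 ! metabolic disease

[Term]
id: DEMO:0000009
name: kidney disease
is_a: DEMO:0000001 ! phenotype

[Term]
id: DEMO:0000010
name: chronic kidney disease
is_a: DEMO:0000009 ! kidney disease
"""


@pytest.fixture
def obo_path(tmp_path):
    p = tmp_path / "demo.obo"
    p.write_text(OBO_FIXTURE, encoding="utf-8")
    return p
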