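"""Two-stage harmonization: candidates, scores, selection, evidence mapping."""

import math

import pytest

from claimtriage.harmonization import (
    HarmonizationConfig,
    OntologyCandidate,
    harmonize_claim,
    identity_score,
    information_content,
    map_to_evidence_entities,
    retrieve_ontology_candidates,
    select_candidates,
)
from claimtriage.encoder import cosine, get_encoder
from claimtriage.kg import ClaimTriple, KnowledgeGraph, OntologyEdge, Taxonomy
from claimtriage.synthetic import GeneratorConfig, generate
from tests.conftest import ent, make_generator_config

PERMISSIVE = HarmonizationConfig(
    min_candidate_similarity=0.4,
    identity_threshold=0.5,
    min_evidence_similarity=0.5,
)


# -- information content ---------------------------------------------------


def chain_ontology(n):
    entities = [ent("ONTOLOGY", f"T{i}", f"term {i}") for i in range(n)]
    edges = [OntologyEdge(f"T{i}", f"T{i+1}") for i in range(n - 1)]
    return KnowledgeGraph(entities, edges)


def test_information_content_closed_forms():
    kg = chain_ontology(4)
    assert information_content(kg, "T0") == 1.0  # leaf
    assert information_content(kg, "T3") == 0.0  # root covering everything
    # mid node with 1 descendant in a 4-term ontology
    assert math.isclose(
        information_content(kg, "T1"), 1 - math.log(2) / math.log(4), abs_tol=1e-12
    )


def test_information_content_mid_node_half():
    # 9 descendants in a 100-term ontology: 1 - log(10)/log(100) = 0.5
    entities = [ent("ONTOLOGY", f"T{i}", f"term {i}") for i in range(100)]
    edges = [OntologyEdge(f"T{i}", "T99") for i in range(10, 99)]
    edges += [OntologyEdge(f"T{i}", "T9") for i in range(9)]
    kg = KnowledgeGraph(entities, edges)
    assert math.isclose(information_content(kg, "T9"), 0.5, abs_tol=1e-12)


def test_information_content_anti_monotone_on_random_trees():
    # ancestors are never more concrete than their descendants
    for seed in range(3):
        kg, _ = generate(GeneratorConfig(seed=seed, n_ontology_terms=30,
                                         n_lit_terms=0, n_traits=0,
                                         n_background_triples=0,
                                         n_background_assocs=0))
        for edge in kg.ontology_edges:
            assert information_content(kg, edge.parent_id) <= information_content(
                kg, edge.child_id
            ) + 1e-12


# -- identity score --------------------------------------------------------


def test_identity_score_examples(glucose_kg):
    assert identity_score("glucose", "CHEBI:17234", glucose_kg) == 0.0
    near = identity_score("Diabetes", "EFO:0000400", glucose_kg)
    far = identity_score("Diabetes", "EFO:0003767", glucose_kg)
    assert 0.0 <= near <= 1.0 and 0.0 <= far <= 1.0
    assert near < far  # "diabetes mellitus" is closer than "inflammatory bowel disease"


# -- candidate retrieval and selection -------------------------------------


def test_exact_label_candidate_ranks_first_with_similarity_one(glucose_kg):
    cands = retrieve_ontology_candidates("glucose", glucose_kg, PERMISSIVE)
    assert cands[0].term_id == "CHEBI:17234"
    assert math.isclose(cands[0].similarity, 1.0, abs_tol=1e-12)
    assert cands[0].identity_score == 0.0


def test_equal_labels_tie_broken_by_term_id():
    entities = [
        ent("ONTOLOGY", "B:2", "same name"),
        ent("ONTOLOGY", "A:1", "same name"),
        ent("ONTOLOGY", "C:3", "root"),
    ]
    edges = [OntologyEdge("A:1", "C:3"), OntologyEdge("B:2", "C:3")]
    kg = KnowledgeGraph(entities, edges)
    cands = retrieve_ontology_candidates("same name", kg, PERMISSIVE)
    assert [c.term_id for c in cands[:2]] == ["A:1", "B:2"]


def test_top_k_candidates_equal_brute_force_on_synthetic_ontology():
    kg, _ = generate(GeneratorConfig(seed=7, n_ontology_terms=100, n_lit_terms=0,
                                     n_traits=0, n_background_triples=0,
                                     n_background_assocs=0))
    cfg = HarmonizationConfig(k_candidates=5, min_candidate_similarity=0.0)
    query = kg.entities(Taxonomy.ONTOLOGY)[17].label
    enc = get_encoder("fallback")
    brute = sorted(
        (
            (e.id, cosine(enc.encode(query), enc.encode(e.label)))
            for e in kg.entities(Taxonomy.ONTOLOGY)
        ),
        key=lambda t: (-t[1], t[0]),
    )[:5]
    got = retrieve_ontology_candidates(query, kg, cfg)
    assert [(c.term_id, pytest.approx(c.similarity)) for c in got] == brute


def cand(term_id, sim, ic, ident):
    return OntologyCandidate(term_id, f"label {term_id}", sim, ic, ident)


def test_selection_rule_and_oracle():
    cfg = HarmonizationConfig(identity_threshold=0.2, ic_range=(0.3, 1.0))
    cands = [
        cand("a", 0.9, 1.0, 0.0),   # passes both
        cand("b", 0.8, 0.2, 0.0),   # ic too low
        cand("c", 0.7, 0.5, 0.3),   # identity too high
        cand("d", 0.6, 0.5, 0.1),   # passes both
    ]
    out, fallback = select_candidates(cands, cfg)
    expected = [
        c.identity_score <= 0.2 and 0.3 <= c.ic_score <= 1.0 for c in cands
    ]
    assert [c.selected for c in out] == expected
    assert not fallback
    assert [c.term_id for c in out] == ["a", "b", "c", "d"]  # order preserved


def test_all_pass_selection():
    out, fallback = select_candidates(
        [cand("a", 0.9, 1.0, 0.0), cand("b", 0.5, 1.0, 0.0)], HarmonizationConfig()
    )
    assert all(c.selected for c in out) and not fallback


def test_fallback_selects_single_top_similarity_candidate():
    cfg = HarmonizationConfig(identity_threshold=0.0)
    cands = [cand("a", 0.7, 1.0, 0.1), cand("b", 0.9, 1.0, 0.1), cand("c", 0.9, 1.0, 0.1)]
    out, fallback = select_candidates(cands, cfg)
    assert fallback
    assert [c.term_id for c in out if c.selected] == ["b"]  # top sim, tie -> id


def test_empty_candidates_yield_empty_selection():
    out, fallback = select_candidates([], HarmonizationConfig())
    assert out == [] and not fallback


def test_strict_mode_disables_fallback():
    cfg = HarmonizationConfig(identity_threshold=0.0, allow_fallback_selection=False)
    out, fallback = select_candidates([cand("a", 0.7, 1.0, 0.5)], cfg)
    assert not fallback and not any(c.selected for c in out)


# -- evidence mapping ------------------------------------------------------


def test_glucose_maps_to_lit_term_and_both_gwas_traits(glucose_kg):
    cands = retrieve_ontology_candidates("glucose", glucose_kg, PERMISSIVE)
    selected, _ = select_candidates(cands, PERMISSIVE)
    selected = [c for c in selected if c.selected]
    lit = map_to_evidence_entities(selected, Taxonomy.LIT_TERM, glucose_kg, PERMISSIVE)
    assert [m.entity.id for m in lit] == ["C0017725"]
    assert math.isclose(lit[0].similarity, 1.0, abs_tol=1e-12)
    traits = map_to_evidence_entities(selected, Taxonomy.TRAIT, glucose_kg, PERMISSIVE)
    assert {m.entity.id for m in traits} == {"ukb-d-30740_irnt", "ukb-d-30740_raw"}


def test_threshold_one_excludes_non_identical_labels(glucose_kg):
    cfg = PERMISSIVE.model_copy(update={"min_evidence_similarity": 1.0})
    cands = retrieve_ontology_candidates("glucose", glucose_kg, cfg)
    selected = [c for c in select_candidates(cands, cfg)[0] if c.selected]
    traits = map_to_evidence_entities(selected, Taxonomy.TRAIT, glucose_kg, cfg)
    assert traits == []


def test_duplicate_evidence_entity_keeps_best_chain(glucose_kg):
    selected = [
        cand("CHEBI:17234", 1.0, 1.0, 0.0),
        cand("EFO:0000400", 0.5, 1.0, 0.0),
    ]
    for c in selected:
        c.selected = True
    # give both candidates their real labels so encoding is meaningful
    selected[0].label = "glucose"
    selected[1].label = "glucose"
    out = map_to_evidence_entities(selected, Taxonomy.LIT_TERM, glucose_kg, PERMISSIVE)
    hit = [m for m in out if m.entity.id == "C0017725"]
    assert len(hit) == 1
    assert hit[0].query_similarity == 1.0  # the higher-similarity chain won


# -- full-claim harmonization ----------------------------------------------


def test_glucose_treats_diabetes_full_chain(glucose_kg):
    claim = ClaimTriple("Glucose", "TREATS", "Diabetes")
    res = harmonize_claim(claim, glucose_kg, PERMISSIVE)
    assert res.subject.selected_term_ids == ["CHEBI:17234"]
    assert res.subject.entity_ids(Taxonomy.LIT_TERM) == {"C0017725"}
    assert res.subject.entity_ids(Taxonomy.TRAIT) == {
        "ukb-d-30740_irnt", "ukb-d-30740_raw"
    }
    assert set(res.object.selected_term_ids) >= {"EFO:0000400"}
    diabetes_family = {"EFO:0000400", "EFO:0004593", "EFO:0009605"}
    assert set(res.object.selected_term_ids) <= diabetes_family
    assert res.object.entity_ids(Taxonomy.LIT_TERM) == {"C0011849"}


def test_side_independence_under_swap(glucose_kg):
    claim = ClaimTriple("Glucose", "TREATS", "Diabetes")
    fwd = harmonize_claim(claim, glucose_kg, PERMISSIVE)
    rev = harmonize_claim(claim.swapped(), glucose_kg, PERMISSIVE)
    assert fwd.subject == rev.object
    assert fwd.object == rev.subject


def test_unmatchable_terms_give_empty_result(glucose_kg):
    claim = ClaimTriple("zzqx qqfv", "CAUSES", "wwnm ppry")
    res = harmonize_claim(claim, glucose_kg, HarmonizationConfig())
    assert not res.has_mappings


def test_tightening_thresholds_never_enlarges_selection(glucose_kg):
    claim = ClaimTriple("Glucose", "TREATS", "Diabetes")
    loose = PERMISSIVE.model_copy(update={"allow_fallback_selection": False})
    tight = loose.model_copy(
        update={
            "min_candidate_similarity": 0.8,
            "identity_threshold": 0.1,
            "min_evidence_similarity": 0.9,
            "ic_range": (0.5, 1.0),
        }
    )
    res_loose = harmonize_claim(claim, glucose_kg, loose)
    res_tight = harmonize_claim(claim, glucose_kg, tight)
    for side in ("subject", "object"):
        sl, st_ = getattr(res_loose, side), getattr(res_tight, side)
        assert set(st_.selected_term_ids) <= set(sl.selected_term_ids)
        for tax in (Taxonomy.LIT_TERM, Taxonomy.TRAIT):
            assert st_.entity_ids(tax) <= sl.entity_ids(tax)


def test_planted_alias_recovery_at_one_edit_per_word():
    """Ontology terms planted as claim labels are recovered as selected
    candidates even when the evidence vocabulary is label-perturbed."""
    n_claims, n_seeds = 10, 5
    hits = total = 0
    for seed in range(n_seeds):
        cfg = make_generator_config(seed, noise=1, n_claims=n_claims)
        kg, truth = generate(cfg)
        for claim_truth in truth.claims:
            for term in (claim_truth.claim.subject_term, claim_truth.claim.object_term):
                cands = retrieve_ontology_candidates(term, kg, HarmonizationConfig())
                selected, _ = select_candidates(cands, HarmonizationConfig())
                total += 1
                labels = [c.label for c in selected if c.selected]
                hits += term in labels
    assert hits / total >= 0.95
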