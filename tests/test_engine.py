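"""Classification engine: predicate groups, rule table, orchestration."""

import numpy as np
import pytest

from claimtriage.engine import (
    EvidenceConfig,
    EvidenceGroup,
    EvidenceType,
    Orientation,
    PredicateGroup,
    classify_association_evidence,
    classify_triple_evidence,
    predicate_group,
    run_query,
)
from claimtriage.harmonization import (
    EvidenceEntityMapping,
    HarmonizationConfig,
    HarmonizationResult,
    SideHarmonization,
)
from claimtriage.kg import (
    AssociationRecord,
    AssociationType,
    ClaimTriple,
    Entity,
    GraphValidationError,
    KnowledgeGraph,
    LiteratureRecord,
    Predicate,
    Taxonomy,
    TripleEvidenceRecord,
)
from claimtriage.synthetic import generate
from tests.conftest import ent, make_generator_config

DIRECTIONAL = [Predicate.AFFECTS, Predicate.CAUSES, Predicate.PRODUCES, Predicate.TREATS]
NON_DIRECTIONAL = [
    Predicate.ASSOCIATED_WITH, Predicate.COEXISTS_WITH, Predicate.INTERACTS_WITH
]


def test_predicate_group_partition():
    for p in DIRECTIONAL:
        assert predicate_group(p) is PredicateGroup.DIRECTIONAL
    for p in NON_DIRECTIONAL:
        assert predicate_group(p) is PredicateGroup.NON_DIRECTIONAL
    with pytest.raises(GraphValidationError, match="CAUSES"):
        predicate_group("REGULATES")


# -- hand-built harmonization over named entity pools ----------------------

S_LITS, O_LITS = ["s1", "s2"], ["o1", "o2"]
S_TRAITS, O_TRAITS = ["ts1", "ts2"], ["to1", "to2"]
EXTRA_LITS, EXTRA_TRAITS = ["x1"], ["tx1"]


def make_side(term, lit_ids, trait_ids):
    def maps(ids, taxonomy):
        return [
            EvidenceEntityMapping(
                ontology_term_id="ONT",
                entity=Entity(taxonomy, i, f"label {i}"),
                similarity=0.9,
                query_similarity=0.9,
            )
            for i in ids
        ]

    return SideHarmonization(
        query_term=term,
        lit_mappings=maps(lit_ids, Taxonomy.LIT_TERM),
        trait_mappings=maps(trait_ids, Taxonomy.TRAIT),
    )


def make_harm():
    return HarmonizationResult(
        subject=make_side("subject term", S_LITS, S_TRAITS),
        object=make_side("object term", O_LITS, O_TRAITS),
    )


def build_kg(triples=(), associations=()):
    entities = [ent("LIT_TERM", i, f"label {i}") for i in S_LITS + O_LITS + EXTRA_LITS]
    entities += [ent("TRAIT", i, f"label {i}") for i in S_TRAITS + O_TRAITS + EXTRA_TRAITS]
    literature = [LiteratureRecord("PMID:1")]
    return KnowledgeGraph(entities, [], triples, associations, literature)


def triple(s, p, o):
    return TripleEvidenceRecord(s, p, o, ("PMID:1",))


def assoc(s, t, atype, p_value):
    return AssociationRecord(s, t, atype, 0.1, 0.05, p_value)


# -- triple-and-literature group ------------------------------------------


def test_reverse_orientation_triple_is_reversal_for_directional_claim():
    kg = build_kg(triples=[triple("o1", Predicate.CAUSES, "s1")])
    claim = ClaimTriple("subject term", "CAUSES", "object term")
    out = classify_triple_evidence(make_harm(), claim, kg)
    assert [(c.type, c.orientation) for c in out] == [
        (EvidenceType.REVERSAL, Orientation.REVERSE)
    ]


def test_non_directional_claim_never_yields_reversal():
    kg = build_kg(
        triples=[
            triple("s1", Predicate.INTERACTS_WITH, "o1"),
            triple("o2", Predicate.INTERACTS_WITH, "s2"),
        ]
    )
    claim = ClaimTriple("subject term", "INTERACTS_WITH", "object term")
    out = classify_triple_evidence(make_harm(), claim, kg)
    assert len(out) == 2
    assert all(c.type is EvidenceType.SUPPORTING for c in out)
    assert all(c.orientation is Orientation.FORWARD for c in out)


def test_both_orientations_of_coexists_triples_all_supporting_deduplicated():
    kg = build_kg(
        triples=[
            triple("s1", Predicate.COEXISTS_WITH, "o1"),
            triple("o1", Predicate.COEXISTS_WITH, "s1"),
        ]
    )
    claim = ClaimTriple("subject term", "COEXISTS_WITH", "object term")
    out = classify_triple_evidence(make_harm(), claim, kg)
    keys = [c.key for c in out]
    assert len(keys) == len(set(keys)) == 2
    assert all(c.type is EvidenceType.SUPPORTING for c in out)


def test_triple_chains_follow_the_matched_orientation():
    kg = build_kg(triples=[triple("o1", Predicate.CAUSES, "s1")])
    claim = ClaimTriple("subject term", "CAUSES", "object term")
    harm = make_harm()
    # make the chains distinguishable per side
    harm.subject.lit_mappings[0] = EvidenceEntityMapping(
        "ONT", Entity(Taxonomy.LIT_TERM, "s1", "label s1"), 0.8, 0.7
    )
    out = classify_triple_evidence(harm, claim, kg)
    assert out[0].subject_chain == (0.7, 0.8)  # claim subject reached rec.object


# -- association group -----------------------------------------------------


def test_directional_claim_association_types():
    pi = 1e-3
    kg = build_kg(
        associations=[
            assoc("ts1", "to1", AssociationType.MR_EVE_MR, 1e-5),   # supporting
            assoc("ts1", "to2", AssociationType.MR_EVE_MR, 0.2),    # insufficient fwd
            assoc("to1", "ts1", AssociationType.MR_EVE_MR, 1e-5),   # reversal
            assoc("to2", "ts2", AssociationType.MR_EVE_MR, 0.5),    # insufficient rev
            assoc("ts2", "to2", AssociationType.GEN_COR, 0.9),      # additional
            assoc("to2", "ts1", AssociationType.PRS, 1e-6),         # additional
            assoc("ts1", "tx1", AssociationType.MR_EVE_MR, 1e-9),   # no object side
        ]
    )
    claim = ClaimTriple("subject term", "CAUSES", "object term")
    out = classify_association_evidence(make_harm(), claim, kg, EvidenceConfig(p_threshold=pi))
    by_type = {}
    for c in out:
        by_type.setdefault(c.type, []).append(c)
    assert [c.key for c in by_type[EvidenceType.SUPPORTING]] == [
        ("ts1", "to1", "MR_EVE_MR")
    ]
    assert [c.key for c in by_type[EvidenceType.REVERSAL]] == [
        ("to1", "ts1", "MR_EVE_MR")
    ]
    insufficient = {c.key: c.orientation for c in by_type[EvidenceType.INSUFFICIENT]}
    assert insufficient == {
        ("ts1", "to2", "MR_EVE_MR"): Orientation.FORWARD,
        ("to2", "ts2", "MR_EVE_MR"): Orientation.REVERSE,
    }
    assert {c.key for c in by_type[EvidenceType.ADDITIONAL]} == {
        ("ts2", "to2", "GEN_COR"), ("to2", "ts1", "PRS")
    }


def test_non_directional_claim_all_types_support_or_insufficient():
    kg = build_kg(
        associations=[
            assoc("ts1", "to1", AssociationType.MR_EVE_MR, 1e-5),
            assoc("to1", "ts2", AssociationType.GEN_COR, 1e-4),
            assoc("ts2", "to2", AssociationType.PRS, 0.7),
        ]
    )
    claim = ClaimTriple("subject term", "ASSOCIATED_WITH", "object term")
    out = classify_association_evidence(make_harm(), claim, kg, EvidenceConfig(p_threshold=1e-3))
    types = {c.key: c.type for c in out}
    assert types == {
        ("ts1", "to1", "MR_EVE_MR"): EvidenceType.SUPPORTING,
        ("to1", "ts2", "GEN_COR"): EvidenceType.SUPPORTING,
        ("ts2", "to2", "PRS"): EvidenceType.INSUFFICIENT,
    }
    assert all(c.type is not EvidenceType.REVERSAL for c in out)


def test_self_pair_association_records_are_excluded():
    kg = build_kg(associations=[assoc("ts1", "ts1", AssociationType.GEN_COR, 1e-5)])
    claim = ClaimTriple("subject term", "ASSOCIATED_WITH", "object term")
    harm = HarmonizationResult(
        subject=make_side("subject term", S_LITS, S_TRAITS),
        object=make_side("object term", O_LITS, O_TRAITS + ["ts1"]),
    )
    out = classify_association_evidence(harm, claim, kg, EvidenceConfig())
    assert out == []


# -- oracle equivalence ----------------------------------------------------


def oracle_rule_table(records, claim_predicate, pi):
    """Independent record-by-record transcription of the rule table."""
    subj_l, obj_l = set(S_LITS), set(O_LITS)
    subj_t, obj_t = set(S_TRAITS), set(O_TRAITS)
    directional_claim = claim_predicate in DIRECTIONAL
    out = {}
    for rec in records:
        if isinstance(rec, TripleEvidenceRecord):
            if rec.predicate is not claim_predicate:
                continue
            fwd = rec.subject_id in subj_l and rec.object_id in obj_l
            rev = rec.subject_id in obj_l and rec.object_id in subj_l
            if fwd:
                out[rec.key] = EvidenceType.SUPPORTING
            elif rev:
                out[rec.key] = (
                    EvidenceType.REVERSAL if directional_claim else EvidenceType.SUPPORTING
                )
        else:
            if rec.source_trait_id == rec.target_trait_id:
                continue
            fwd = rec.source_trait_id in subj_t and rec.target_trait_id in obj_t
            rev = rec.source_trait_id in obj_t and rec.target_trait_id in subj_t
            if not (fwd or rev):
                continue
            if directional_claim:
                if rec.directional:
                    if rec.p_value >= pi:
                        out[rec.key] = EvidenceType.INSUFFICIENT
                    elif fwd:
                        out[rec.key] = EvidenceType.SUPPORTING
                    else:
                        out[rec.key] = EvidenceType.REVERSAL
                else:
                    out[rec.key] = EvidenceType.ADDITIONAL
            else:
                out[rec.key] = (
                    EvidenceType.SUPPORTING if rec.p_value < pi else EvidenceType.INSUFFICIENT
                )
    return out


@pytest.mark.parametrize("predicate", list(Predicate))
def test_classification_equals_rule_table_oracle(predicate):
    rng = np.random.default_rng(hash(predicate.value) % 2**31)
    lit_pool = S_LITS + O_LITS + EXTRA_LITS
    trait_pool = S_TRAITS + O_TRAITS + EXTRA_TRAITS
    triples, seen_t = [], set()
    for _ in range(100):
        s, o = rng.choice(lit_pool, 2, replace=False)
        p = list(Predicate)[rng.integers(len(Predicate))]
        if (s, p.value, o) not in seen_t:
            seen_t.add((s, p.value, o))
            triples.append(triple(s, p, o))
    assocs, seen_a = [], set()
    for _ in range(100):
        s, t = rng.choice(trait_pool, 2, replace=False)
        atype = list(AssociationType)[rng.integers(3)]
        if (s, t, atype.value) not in seen_a:
            seen_a.add((s, t, atype.value))
            assocs.append(assoc(s, t, atype, float(rng.uniform(1e-6, 1.0))))
    kg = build_kg(triples=triples, associations=assocs)
    pi = 1e-2
    claim = ClaimTriple("subject term", predicate, "object term")
    harm = make_harm()
    got = {
        c.key: c.type
        for c in classify_triple_evidence(harm, claim, kg)
        + classify_association_evidence(harm, claim, kg, EvidenceConfig(p_threshold=pi))
    }
    expected = oracle_rule_table(kg.triples + kg.associations, predicate, pi)
    assert got == expected


# -- run_query orchestration -----------------------------------------------


def test_run_query_counts_match_planted_ground_truth():
    cfg = make_generator_config(seed=3, noise=0, n_claims=2)
    kg, truth = generate(cfg)
    claim_truth = truth.claims[0]  # a directional plant: 2/1 triples, 2/1/2/2 assocs
    rep = run_query(claim_truth.claim, kg)
    assert rep.status == "ok"
    assert rep.aggregate("TRIPLE_LIT", "SUPPORTING")["count"] == 2
    assert rep.aggregate("TRIPLE_LIT", "REVERSAL")["count"] == 1
    assert rep.aggregate("ASSOC", "SUPPORTING")["count"] == 2
    assert rep.aggregate("ASSOC", "REVERSAL")["count"] == 1
    assert rep.aggregate("ASSOC", "INSUFFICIENT")["count"] == 2
    assert rep.aggregate("ASSOC", "ADDITIONAL")["count"] == 2


def test_run_query_no_mapped_entities_status(glucose_kg):
    rep = run_query(ClaimTriple("qqq zzz", "CAUSES", "vvv www"), glucose_kg)
    assert rep.status == "no mapped entities"
    assert all(cell["count"] == 0 for cell in rep.aggregates)


def test_run_query_is_deterministic(glucose_kg):
    claim = ClaimTriple("Glucose", "TREATS", "Diabetes")
    cfg = HarmonizationConfig(min_candidate_similarity=0.4, identity_threshold=0.5,
                              min_evidence_similarity=0.5)
    r1 = run_query(claim, glucose_kg, cfg)
    r2 = run_query(claim, glucose_kg, cfg)
    assert r1.to_json() == r2.to_json()


def test_partition_every_item_gets_exactly_one_type():
    cfg = make_generator_config(seed=11, noise=0, n_claims=4)
    kg, truth = generate(cfg)
    for claim_truth in truth.claims:
        rep = run_query(claim_truth.claim, kg)
        keys = []
        for g in EvidenceGroup:
            for t in EvidenceType:
                for item in rep.items(g, t):
                    if g is EvidenceGroup.TRIPLE_LIT:
                        keys.append((item["subject_id"], item["predicate"],
                                     item["object_id"]))
                    else:
                        keys.append((item["source_trait_id"], item["target_trait_id"],
                                     item["assoc_type"]))
        assert len(keys) == len(set(keys))
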