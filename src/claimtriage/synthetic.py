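"""Seeded synthetic knowledge graphs with planted, fully-known evidence.

The generator emits graphs with the same schema as the real evidence store:
an is-a ontology tree, literature-term and trait vocabularies whose labels
are noise-perturbed copies of ontology labels plus unrelated distractors,
background literature triples with 1 + Poisson(lambda) source articles, and
background trait associations with normally distributed standardized
effects.  On top of the background it plants claims with a requested
composition of evidence — so many supporting triples, reversal associations,
and so on — constructed to satisfy the classification rule table exactly
under the configured P-value threshold.  The emitted ground truth lists the
record keys of every planted item together with its designated evidence
type, which makes end-to-end recovery measurable.

Everything is reproducible from the seed: the same configuration always
produces byte-identical graph files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .engine import EvidenceGroup, EvidenceType, PredicateGroup, predicate_group
from .kg import (
    AssociationRecord,
    AssociationType,
    ClaimTriple,
    Entity,
    KnowledgeGraph,
    LiteratureRecord,
    OntologyEdge,
    Predicate,
    Taxonomy,
    TripleEvidenceRecord,
    save_graph,
)
from .scoring import normal_critical_value, two_sided_p

__all__ = [
    "PlantedClaim",
    "GeneratorConfig",
    "GeneratorConfigError",
    "GroundTruth",
    "PlantedClaimTruth",
    "generate",
    "generate_to_dir",
    "perturb_label",
    "synthesize_labels",
    "evaluate_recovery",
]


class GeneratorConfigError(ValueError):
    """The requested graph is infeasible (e.g. reversal for a symmetric claim)."""


class PlantedClaim(BaseModel):
    """A claim to plant, with its designated evidence composition."""

    subject_label: str
    predicate: Predicate
    object_label: str
    n_supporting_triples: int = Field(default=0, ge=0)
    n_reversal_triples: int = Field(default=0, ge=0)
    n_supporting_assocs: int = Field(default=0, ge=0)
    n_reversal_assocs: int = Field(default=0, ge=0)
    n_insufficient_assocs: int = Field(default=0, ge=0)
    n_additional_assocs: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_feasible(self):
        if predicate_group(self.predicate) is PredicateGroup.NON_DIRECTIONAL:
            bad = {
                "n_reversal_triples": self.n_reversal_triples,
                "n_reversal_assocs": self.n_reversal_assocs,
                "n_additional_assocs": self.n_additional_assocs,
            }
            offending = [k for k, v in bad.items() if v > 0]
            if offending:
                raise GeneratorConfigError(
                    f"plant ({self.subject_label!r} {self.predicate.value} "
                    f"{self.object_label!r}): {', '.join(offending)} requested, but "
                    "reversal and additional evidence only exist for directional claims"
                )
        if not self.subject_label or not self.object_label:
            raise GeneratorConfigError("planted claim labels must be non-empty")
        return self

    @property
    def claim(self) -> ClaimTriple:
        return ClaimTriple(self.subject_label, self.predicate, self.object_label)


class GeneratorConfig(BaseModel):
    n_ontology_terms: int = Field(default=60, ge=2)
    tree_branching: int = Field(default=3, ge=1)
    n_lit_terms: int = Field(default=80, ge=0)
    n_traits: int = Field(default=60, ge=0)
    n_background_triples: int = Field(default=120, ge=0)
    n_background_assocs: int = Field(default=150, ge=0)
    label_noise_level: int = Field(default=0, ge=0, le=2)
    literature_lambda: float = Field(default=0.6, ge=0.0)
    p_threshold: float = Field(default=1e-3, gt=0.0, lt=1.0)
    planted_claims: list = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check_plants(self):
        self.planted_claims = [
            p if isinstance(p, PlantedClaim) else PlantedClaim(**p)
            for p in self.planted_claims
        ]
        labels = [p.subject_label for p in self.planted_claims] + [
            p.object_label for p in self.planted_claims
        ]
        if len(set(labels)) != len(labels):
            raise GeneratorConfigError("planted claim labels must be pairwise distinct")
        return self


@dataclass
class PlantedClaimTruth:
    """Record keys of all planted evidence for one claim, by (group, type)."""

    claim: ClaimTriple
    records: dict  # (EvidenceGroup, EvidenceType) -> list of record keys

    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values())

    def to_dict(self) -> dict:
        return {
            "claim": {
                "subject_term": self.claim.subject_term,
                "predicate": self.claim.predicate.value,
                "object_term": self.claim.object_term,
            },
            "records": {
                f"{g.value}/{t.value}": [list(k) for k in keys]
                for (g, t), keys in self.records.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedClaimTruth":
        records = {}
        for cell, keys in d["records"].items():
            g, t = cell.split("/")
            records[(EvidenceGroup(g), EvidenceType(t))] = [tuple(k) for k in keys]
        return cls(claim=ClaimTriple(**d["claim"]), records=records)


@dataclass
class GroundTruth:
    claims: list

    def to_dict(self) -> dict:
        return {"claims": [c.to_dict() for c in self.claims]}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(claims=[PlantedClaimTruth.from_dict(c) for c in d["claims"]])


# -- label synthesis and perturbation --------------------------------------

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for _ in range(n_syllables):
        parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        parts.append(_VOWELS[rng.integers(len(_VOWELS))])
    return "".join(parts)


def _unique_words(rng: np.random.Generator, n: int, taken: set) -> list:
    words = []
    while len(words) < n:
        w = _word(rng, int(rng.integers(4, 6)))  # 8 or 10 characters
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def synthesize_labels(n: int, rng: np.random.Generator, words_per_label: int = 3) -> list:
    """Synthesize ``n`` distinct multi-word labels from a fresh word pool."""
    taken: set = set()
    words = _unique_words(rng, n * words_per_label, taken)
    return [
        " ".join(words[i * words_per_label : (i + 1) * words_per_label])
        for i in range(n)
    ]


def perturb_label(label: str, noise_level: int, rng: np.random.Generator) -> str:
    """Apply ``noise_level`` random single-character edits to each word."""
    if noise_level not in (0, 1, 2):
        raise GeneratorConfigError(f"noise_level must be 0, 1 or 2, got {noise_level}")
    if noise_level == 0:
        return label
    alphabet = _CONSONANTS + _VOWELS
    words = []
    for word in label.split():
        chars = list(word)
        for _ in range(noise_level):
            op = ("substitute", "delete", "insert")[rng.integers(3)]
            if op == "delete" and len(chars) <= 3:
                op = "substitute"
            pos = int(rng.integers(len(chars)))
            letter = alphabet[rng.integers(len(alphabet))]
            if op == "substitute":
                chars[pos] = letter
            elif op == "delete":
                del chars[pos]
            else:
                chars.insert(pos, letter)
        words.append("".join(chars))
    return " ".join(words)


# -- generation ------------------------------------------------------------

_VARIANT_SUFFIXES = ["", " b", " c", " d", " e", " f", " g", " h"]


def _n_variants_for(*capacity_requirements) -> int:
    """Smallest v such that every (needed, slots_per_pair) requirement fits v**2 pairs."""
    v = 1
    while any(needed > slots * v * v for needed, slots in capacity_requirements):
        v += 1
    return v


def _variant_labels(base: str, v: int, noise: int, rng: np.random.Generator) -> list:
    if v > len(_VARIANT_SUFFIXES):
        raise GeneratorConfigError(
            f"planted claim needs {v} entity variants per side; at most "
            f"{len(_VARIANT_SUFFIXES)} supported"
        )
    return [perturb_label(base, noise, rng) + _VARIANT_SUFFIXES[i] for i in range(v)]


def generate(cfg: GeneratorConfig) -> tuple:
    """Build a synthetic graph and its ground truth. Deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    taken_words: set = set()

    # -- ontology: random tree with bounded branching ----------------------
    n_base = cfg.n_ontology_terms
    base_words = _unique_words(rng, n_base * 3, taken_words)
    onto_labels = [" ".join(base_words[i * 3 : (i + 1) * 3]) for i in range(n_base)]
    onto_ids = [f"EFO:{i:07d}" for i in range(n_base)]
    edges = []
    child_counts = [0] * n_base
    for i in range(1, n_base):
        open_parents = [j for j in range(i) if child_counts[j] < cfg.tree_branching]
        parent = open_parents[rng.integers(len(open_parents))] if open_parents else int(
            rng.integers(i)
        )
        child_counts[parent] += 1
        edges.append(OntologyEdge(onto_ids[i], onto_ids[parent]))

    # planted claim terms join the ontology as leaf terms
    for plant in cfg.planted_claims:
        for label in (plant.subject_label, plant.object_label):
            term_id = f"EFO:{len(onto_ids):07d}"
            parent = int(rng.integers(len(onto_ids)))
            onto_ids.append(term_id)
            onto_labels.append(label)
            edges.append(OntologyEdge(term_id, onto_ids[parent]))

    entities = [
        Entity(Taxonomy.ONTOLOGY, tid, lbl)
        for tid, lbl in zip(onto_ids, onto_labels)
    ]

    # -- evidence vocabularies --------------------------------------------
    noise = cfg.label_noise_level
    lit_ids: list = []
    trait_ids: list = []
    next_lit = [1]
    next_trait = [30001]

    def new_lit(label: str) -> str:
        lid = f"C{next_lit[0]:07d}"
        next_lit[0] += 1
        entities.append(
            Entity(Taxonomy.LIT_TERM, lid, label, semantic_types=frozenset({"dsyn"}))
        )
        lit_ids.append(lid)
        return lid

    def new_trait(label: str) -> str:
        tid = f"ukb-d-{next_trait[0]}"
        next_trait[0] += 1
        entities.append(Entity(Taxonomy.TRAIT, tid, label))
        trait_ids.append(tid)
        return tid

    # per-plant evidence vocabulary: enough label variants per side to hold
    # the requested number of distinct record keys
    plant_lits: dict = {}
    plant_traits: dict = {}
    for plant in cfg.planted_claims:
        directional = predicate_group(plant.predicate) is PredicateGroup.DIRECTIONAL
        v_lit = _n_variants_for(
            (plant.n_supporting_triples, 1), (plant.n_reversal_triples, 1)
        )
        if directional:
            v_trait = _n_variants_for(
                (plant.n_supporting_assocs + plant.n_insufficient_assocs, 1),
                (plant.n_reversal_assocs, 1),
                (plant.n_additional_assocs, 2),
            )
        else:
            v_trait = _n_variants_for(
                (plant.n_supporting_assocs + plant.n_insufficient_assocs, 3)
            )
        for label in (plant.subject_label, plant.object_label):
            plant_lits[label] = [
                new_lit(lbl) for lbl in _variant_labels(label, v_lit, noise, rng)
            ]
            plant_traits[label] = [
                new_trait(lbl) for lbl in _variant_labels(label, v_trait, noise, rng)
            ]

    # copies of base ontology terms plus unrelated distractor labels
    background_lits: list = []
    background_traits: list = []
    n_copies_lit = min(n_base, cfg.n_lit_terms)
    for i in range(n_copies_lit):
        background_lits.append(new_lit(perturb_label(onto_labels[i], noise, rng)))
    n_copies_trait = min(n_base, cfg.n_traits)
    for i in range(n_copies_trait):
        background_traits.append(new_trait(perturb_label(onto_labels[i], noise, rng)))
    n_distract_lit = cfg.n_lit_terms - n_copies_lit
    n_distract_trait = cfg.n_traits - n_copies_trait
    distract_words = _unique_words(rng, (n_distract_lit + n_distract_trait) * 3, taken_words)
    w = iter(distract_words)
    for _ in range(n_distract_lit):
        background_lits.append(new_lit(" ".join(next(w) for _ in range(3))))
    for _ in range(n_distract_trait):
        background_traits.append(new_trait(" ".join(next(w) for _ in range(3))))

    # -- literature + background triples ----------------------------------
    literature: list = []
    next_article = [10_000_000]

    def new_articles(n: int) -> tuple:
        out = []
        for _ in range(n):
            aid = f"PMID:{next_article[0]}"
            next_article[0] += 1
            literature.append(
                LiteratureRecord(aid, title=f"synthetic article {aid}")
            )
            out.append(aid)
        return tuple(out)

    def literature_count() -> int:
        return 1 + int(rng.poisson(cfg.literature_lambda))

    triples: list = []
    triple_keys: set = set()
    predicates = list(Predicate)
    attempts = 0
    while len(triples) < cfg.n_background_triples and attempts < cfg.n_background_triples * 50:
        attempts += 1
        if len(background_lits) < 2:
            break
        i, j = rng.choice(len(background_lits), size=2, replace=False)
        pred = predicates[rng.integers(len(predicates))]
        key = (background_lits[i], pred.value, background_lits[j])
        if key in triple_keys:
            continue
        triple_keys.add(key)
        triples.append(
            TripleEvidenceRecord(
                background_lits[i], pred, background_lits[j],
                new_articles(literature_count()),
            )
        )

    # -- background associations ------------------------------------------
    assoc_types = list(AssociationType)
    associations: list = []
    assoc_keys: set = set()

    def draw_se() -> float:
        return float(rng.uniform(0.05, 0.5))

    attempts = 0
    while len(associations) < cfg.n_background_assocs and attempts < cfg.n_background_assocs * 50:
        attempts += 1
        if len(background_traits) < 2:
            break
        i, j = rng.choice(len(background_traits), size=2, replace=False)
        atype = assoc_types[rng.integers(len(assoc_types))]
        key = (background_traits[i], background_traits[j], atype.value)
        if key in assoc_keys:
            continue
        assoc_keys.add(key)
        se = draw_se()
        effect = float(rng.normal()) * se
        associations.append(
            AssociationRecord(
                background_traits[i], background_traits[j], atype,
                effect, se, two_sided_p(effect, se),
            )
        )

    # -- planted evidence ---------------------------------------------------
    z_pi = normal_critical_value(cfg.p_threshold)

    def planted_assoc(source, target, atype, significant: bool):
        se = draw_se()
        z = (
            float(rng.uniform(1.5, 3.0)) * z_pi
            if significant
            else float(rng.uniform(0.1, 0.8)) * z_pi
        )
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effect = sign * z * se
        rec = AssociationRecord(source, target, atype, effect, se, two_sided_p(effect, se))
        associations.append(rec)
        return rec.key

    truths = []
    for plant in cfg.planted_claims:
        directional = predicate_group(plant.predicate) is PredicateGroup.DIRECTIONAL
        s_lits = plant_lits[plant.subject_label]
        o_lits = plant_lits[plant.object_label]
        s_traits = plant_traits[plant.subject_label]
        o_traits = plant_traits[plant.object_label]
        records: dict = {}

        def put(group, etype, key):
            records.setdefault((group, etype), []).append(key)

        fwd_pairs = list(product(s_lits, o_lits))
        for s, o in fwd_pairs[: plant.n_supporting_triples]:
            rec = TripleEvidenceRecord(
                s, plant.predicate, o, new_articles(literature_count())
            )
            triples.append(rec)
            put(EvidenceGroup.TRIPLE_LIT, EvidenceType.SUPPORTING, rec.key)
        rev_pairs = list(product(o_lits, s_lits))
        for o, s in rev_pairs[: plant.n_reversal_triples]:
            rec = TripleEvidenceRecord(
                o, plant.predicate, s, new_articles(literature_count())
            )
            triples.append(rec)
            put(EvidenceGroup.TRIPLE_LIT, EvidenceType.REVERSAL, rec.key)

        if directional:
            mr_fwd = iter(product(s_traits, o_traits))
            for _ in range(plant.n_supporting_assocs):
                s, o = next(mr_fwd)
                key = planted_assoc(s, o, AssociationType.MR_EVE_MR, True)
                put(EvidenceGroup.ASSOC, EvidenceType.SUPPORTING, key)
            for _ in range(plant.n_insufficient_assocs):
                s, o = next(mr_fwd)
                key = planted_assoc(s, o, AssociationType.MR_EVE_MR, False)
                put(EvidenceGroup.ASSOC, EvidenceType.INSUFFICIENT, key)
            mr_rev = iter(product(o_traits, s_traits))
            for _ in range(plant.n_reversal_assocs):
                o, s = next(mr_rev)
                key = planted_assoc(o, s, AssociationType.MR_EVE_MR, True)
                put(EvidenceGroup.ASSOC, EvidenceType.REVERSAL, key)
            extra = iter(
                (pair, atype)
                for pair in product(s_traits, o_traits)
                for atype in (AssociationType.GEN_COR, AssociationType.PRS)
            )
            for _ in range(plant.n_additional_assocs):
                (s, o), atype = next(extra)
                key = planted_assoc(s, o, atype, bool(rng.random() < 0.5))
                put(EvidenceGroup.ASSOC, EvidenceType.ADDITIONAL, key)
        else:
            combos = iter(
                (pair, atype)
                for pair in product(s_traits, o_traits)
                for atype in assoc_types
            )
            for _ in range(plant.n_supporting_assocs):
                (s, o), atype = next(combos)
                key = planted_assoc(s, o, atype, True)
                put(EvidenceGroup.ASSOC, EvidenceType.SUPPORTING, key)
            for _ in range(plant.n_insufficient_assocs):
                (s, o), atype = next(combos)
                key = planted_assoc(s, o, atype, False)
                put(EvidenceGroup.ASSOC, EvidenceType.INSUFFICIENT, key)

        truths.append(PlantedClaimTruth(claim=plant.claim, records=records))

    kg = KnowledgeGraph(entities, edges, triples, associations, literature)
    return kg, GroundTruth(claims=truths)


def generate_to_dir(cfg: GeneratorConfig, out_dir: "str | Path") -> tuple:
    """Generate, write the graph files plus manifest and ground truth."""
    out_dir = Path(out_dir)
    kg, truth = generate(cfg)
    save_graph(kg, out_dir)
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.seed,
        "ground_truth": "ground_truth.json",
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return kg, truth


# -- recovery measurement ---------------------------------------------------


def evaluate_recovery(
    kg: KnowledgeGraph,
    truth: GroundTruth,
    harm_cfg=None,
    ev_cfg=None,
) -> tuple:
    """Run every planted claim and count ground-truth records recovered
    under their designated (group, type).  Returns (n_recovered, n_total).
    """
    from .engine import run_query

    recovered = 0
    total = 0
    for claim_truth in truth.claims:
        rep = run_query(claim_truth.claim, kg, harm_cfg, ev_cfg)
        for (group, etype), keys in claim_truth.records.items():
            found = set()
            for item in rep.items(group, etype):
                if group is EvidenceGroup.TRIPLE_LIT:
                    found.add((item["subject_id"], item["predicate"], item["object_id"]))
                else:
                    found.add(
                        (item["source_trait_id"], item["target_trait_id"], item["assoc_type"])
                    )
            total += len(keys)
            recovered += sum(1 for k in keys if tuple(k) in found)
    return recovered, total
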