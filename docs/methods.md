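# Methods

This note documents the models and procedures implemented in `claimtriage`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Problem setting

A *claim triple* is a statement `subject PREDICATE object` over free-text
biomedical terms, with the predicate drawn from a fixed seven-element set of
UMLS-style relationships. The evidence store is a knowledge graph with
three entity taxonomies — ontology terms connected by is-a edges (a DAG
with at least one root), literature-vocabulary terms, and GWAS traits — and
two evidence record kinds: literature-derived semantic triples (each backed
by ≥ 1 source articles) and trait-pair statistical associations carrying
effect size, standard error and P-value (Mendelian randomization estimates
are directional; genetic correlations and polygenic-score associations are
not). The task is to decide, for a given claim, which records bear on it
and how, and to rank them.

## Entity harmonization

Claim terms rarely match evidence vocabularies verbatim, so harmonization
runs in two stages with the ontology as the bridge.

**Stage 1 (claim term → ontology candidates).** All ontology labels (plus
synonyms, when present and enabled) are encoded and ranked by cosine
similarity to the encoded claim term; the top `k_candidates` with
similarity ≥ `min_candidate_similarity` become candidates. Each candidate
carries two further scores:

* *information content* `IC(t) = 1 − log(d(t)+1)/log(N)`, where `d(t)` is
  the number of is-a descendants and `N` the ontology size. Leaves score
  1 (maximally concrete); a root covering the whole ontology scores 0.
  `IC` is anti-monotone along is-a paths by construction, since a
  descendant's descendant set is a strict subset of its ancestor's.
* *identity score*, an inferred distance between the query term and the
  candidate (lower = closer). The default estimator is
  `1 − cosine(encode(query), encode(label))` clamped to [0, 1]; the
  estimator is pluggable through the same registry mechanism as encoders,
  so a trained cross-encoder distance model can be substituted.

A candidate is *selected* iff its identity score ≤ `identity_threshold` and
its IC lies inside `ic_range`. If nothing qualifies, the single
highest-similarity candidate is selected as a flagged fallback (disable
with `allow_fallback_selection: false` for strict mode); this keeps
permissive exploratory queries from dead-ending on threshold choices.

**Stage 2 (ontology term → evidence entities).** Each selected ontology
term is mapped, by the same encoder similarity, to the top `k_evidence`
entities of each evidence taxonomy with similarity ≥
`min_evidence_similarity`. When two ontology terms reach the same evidence
entity, the chain with the larger similarity product is kept. Every
retained chain records its two per-step similarities for scoring.

### Defaults

| Parameter                  | Default    | Rationale                                      |
|----------------------------|------------|------------------------------------------------|
| `k_candidates`             | 10         | enough to cover term families without noise    |
| `min_candidate_similarity` | 0.70       | conservative stage-1 floor                     |
| `identity_threshold`       | 0.20       | selects near-identical candidates only         |
| `ic_range`                 | [0.3, 1.0] | excludes near-root umbrella terms              |
| `min_evidence_similarity`  | 0.60       | calibrated to the trigram encoder (below)      |
| `k_evidence`               | 5          | covers duplicate GWAS variants of one trait    |
| `p_threshold` (π)          | 1e-3       | sub-0.05, reflecting the multiple-testing context of systematic association scans |

`min_evidence_similarity` is deliberately calibrated to the similarity
scale of the *active encoder*. Under the trigram fallback, a label
differing by one character edit per word scores ≈ (l−2)/(l+1) per word of
length l — about 0.65–0.75 for realistic word lengths — so 0.60 admits
close variants while the disjoint-vocabulary distractors in the test
fixtures stay far below it (≈ 0.0–0.2). Trained sentence encoders compress
near-synonyms into the 0.85–0.92 band, and deployments using one should
raise this threshold accordingly (0.85 is a sensible default there). All
thresholds are exposed in the config file and as CLI flags.

## The fallback encoder

The `fallback` encoder lowercases and whitespace-normalizes text, pads it
with one space on each side, hashes each character trigram into 256 buckets
with keyed BLAKE2b (fixed key, part of the compatibility contract), and
L2-normalizes the counts. It is a pure function, identical across runs and
platforms, which makes every downstream number reproducible without model
weights. It measures surface similarity only: it has no notion of synonymy
("renal" vs "kidney") or abbreviation. Any vector model can be plugged in
via `register_encoder(name, factory)` and selected by name in the config.

## Evidence classification

Predicates partition into directional {AFFECTS, CAUSES, PRODUCES, TREATS}
and non-directional {ASSOCIATED_WITH, COEXISTS_WITH, INTERACTS_WITH}.
With S/O the evidence entities harmonized to the claim's subject/object
sides and π the P-value threshold:

| Claim group     | Evidence group | Supporting          | Reversal       | Insufficient           | Additional             |
|-----------------|----------------|---------------------|----------------|------------------------|------------------------|
| directional     | triple & lit.  | S −P→ O             | O −P→ S        | —                      | —                      |
| directional     | association    | S→O, directional, p < π | O→S, directional, p < π | either orientation, p ≥ π | non-directional record |
| non-directional | triple & lit.  | S −P− O (either orientation) | —     | —                      | —                      |
| non-directional | association    | any type, p < π     | —              | any type, p ≥ π        | —                      |

Decisions taken where the rule table leaves room:

* *Insufficient covers both orientations* of a directional claim, with the
  orientation recorded, so a report can state whether missing reversal
  evidence reflects absent results or merely weak ones.
* *Additional ignores π* by default (`additional_requires_p` can impose
  it): it is context, not a hypothesis test.
* *Orientation ties*: if an entity harmonizes to both sides, a record can
  match both orientations; supporting takes precedence and each record is
  classified exactly once (the partition property is tested).
* *Self-pairs* (source trait = target trait) are excluded and logged.
* `AssociationRecord.directional` defaults from the association type (MR
  directional, GEN_COR/PRS not) but is data-driven per record, so a source
  with directional PRS results can override it.

Reversal symmetry follows from the rules: for directional claims the
REVERSAL set of `S P O` equals the SUPPORTING set of `O P S` item for item
whenever the two sides harmonize to disjoint entity sets (verified on 50
seeded graphs).

## Scoring

* `mapping_score = s₁·s₂·s₃·s₄`, the product of the per-step similarities
  of the subject and object chains. Chains of exact matches score 1;
  chains with per-step similarities in [0.85, 0.92] give composites in
  [0.522, 0.717].
* `strength_score_triple(n) = 1 + log10(n)` for n source articles:
  1 at the modal single-article triple, 2 at 10 articles, ≈ 2.3 at 20.
* `strength_score_assoc = |effect/SE| / z(π)` with z(π) the two-sided
  standard-normal critical value: exactly 1 at the significance boundary,
  > 1 for items passing π, < 1 for insufficient ones. Classification uses
  the record's P-value, not the score, so a boundary item (p = π) is
  insufficient.
* `evidence_score = mapping_score × strength_score`; aggregates are plain
  sums (plus counts) per (group, type) cell, so users can read volume and
  strength separately. When several chains reach one item, the
  max-product chain's mapping score is used (consistent with the stage-2
  dedup rule).

The three formulas are isolated pure functions; alternative formulations
can be swapped in without touching the engine.

## Synthetic graph generator

`claimtriage.synthetic.generate` emulates the evidence store's schema and
summary statistics:

* ontology: a random tree with bounded branching and synthesized
  three-word pseudo-labels (8–10 characters per word); planted claim terms
  join as leaf terms, so they are concrete (IC = 1) and selectable;
* evidence vocabularies: noise-perturbed copies of ontology labels
  (`label_noise_level` ∈ {0, 1, 2} single-character edits per word) plus
  distractor labels drawn from a disjoint word pool, so true matches and
  distractors are separated by a wide similarity margin;
* literature volume: 1 + Poisson(λ), λ = 0.6 by default — mode 1 with a
  thin upper tail, matching the typical profile of literature-triple
  corpora; background associations draw SE ~ U(0.05, 0.5), effect ~
  N(0, 1)·SE, with the P-value computed from the two-sided normal test
  (internal consistency with the scoring module is tested to 1e-12);
* planted evidence: records constructed to satisfy the rule table exactly
  under the configured π — supporting/reversal associations get
  |effect/SE| between 1.5·z(π) and 3·z(π), insufficient ones between
  0.1·z(π) and 0.8·z(π); per-side entity variants (suffixed labels,
  emulating duplicate GWAS variants of one trait) provide enough distinct
  record keys for the requested counts. Infeasible plants (reversal or
  additional evidence for a non-directional predicate) are rejected before
  generation.

Everything derives from one `numpy` generator seeded from the config, so
identical configurations produce byte-identical files.

**What passing tests show, and what they do not.** Recovery experiments
(10 planted claims × 5 seeds: 100% of planted records recovered under
their designated type at noise 0 and ≥ 95% at noise 1, under default
configuration) validate the retrieval, classification and scoring logic
against ground truth. They do not validate linguistic robustness on real
vocabularies: real UMLS/EFO/GWAS label variation involves synonymy, word
order and abbreviation, which the edit-noise model does not emulate and
the trigram encoder does not capture. On real data those gaps are the
encoder's burden, which is why the encoder is the designated plug-in seam.

## Numerical and procedural choices

* Cosine similarity is clipped to [−1, 1] to absorb floating-point drift;
  zero-norm vectors (e.g. empty labels) get similarity 0 rather than an
  error, so degenerate rows cannot abort a batch run.
* All ranked lists break ties by id ascending; all list-returning queries
  sort by (primary id, secondary id); reports serialize with a stable key
  order and scores rounded to 6 decimals — repeated runs are
  byte-identical.
* Literature triples sharing a (subject, predicate, object) key are merged
  at load with the union of their article lists; the key is the record
  identity throughout.
* Problem sizes in the test suite (graphs of ~40 ontology terms / ~50
  literature terms / ~40 traits, stores of ≤ 200 records, 50 seeds for the
  symmetry suite) were chosen as the smallest sizes at which every
  mechanism under test — duplicate trait variants, both orientations, all
  four types, background distractors — is exercised simultaneously.

## Known limitations

* No free-text claim parsing: claims enter as ready-made triples, and an
  external parser can be adapted via `cli.claims_from_parser`.
* The trigram fallback measures surface similarity only (see above).
* Association evidence is taken at face value: no meta-analytic pooling,
  no instrument-validity checks, no recomputation of P-values beyond the
  normal approximation used for consistency checks.
* Semantic-type codes on literature terms are stored but not used as a
  retrieval filter by default; they are available for optional downstream
  filtering.
* Scores order evidence for triage; they are not calibrated posterior
  beliefs, and items should be inspected at source before conclusions are
  drawn.
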