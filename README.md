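# claimtriage

Evidence triangulation for biomedical claim triples over an offline
knowledge graph.

Epidemiological claims — "Obesity CAUSES Heart failure", "Glucose TREATS
Diabetes" — can be checked against two very different kinds of evidence:
literature-derived semantic triples (with their source articles) and
systematic statistical associations between GWAS traits (Mendelian
randomization estimates, genetic correlations, polygenic-score
associations). Combining strands of evidence with different bias structures
is *triangulation*; the practical obstacles are that the claim's terms, the
literature vocabulary, and the GWAS trait names live in different
taxonomies, and that a retrieved pile of evidence needs classifying and
prioritizing before a human can use it.

`claimtriage` implements that pipeline end to end, for researchers who want
to screen claims (from preprints, abstracts, grant text parsed elsewhere)
against their own node/edge tables without a database server:

1. **Entity harmonization** (two stages). The claim's subject and object
   terms are mapped to candidate ontology terms by embedding similarity;
   candidates are filtered by an *identity score* (inferred distance to the
   query term, lower = closer) and an *information-content score*
   `IC(t) = 1 − log(|descendants(t)|+1)/log(N)` (concreteness in the
   ontology). Selected ontology terms are then mapped, again by similarity,
   to evidence entities: literature-vocabulary terms and GWAS traits.
2. **Evidence retrieval and classification.** Predicates split into
   directional (AFFECTS, CAUSES, PRODUCES, TREATS) and non-directional
   (ASSOCIATED_WITH, COEXISTS_WITH, INTERACTS_WITH) groups. Every retrieved
   item gets exactly one evidence type: *supporting* (same predicate and
   orientation; for associations additionally P < π), *reversal* (supports
   the direction-swapped claim; directional claims only), *insufficient*
   (association with P ≥ π), or *additional* (non-directional association
   context for a directional claim).
3. **Scoring.** Each item's *mapping score* is the product of the four
   harmonization similarities; its *strength score* is `1 + log10(n)` for a
   triple with `n` source articles, or `|effect/SE| / z(π)` for an
   association (exactly 1 at the significance boundary); the *evidence
   score* is their product, summed per (group, type) cell for
   prioritization.

Text-to-vector encoding is pluggable; the built-in `fallback` encoder is a
deterministic hashed character-trigram model, so everything runs offline
and reproducibly. A seeded synthetic-graph generator plants claims with a
known evidence composition, which makes the whole pipeline testable against
ground truth.

## Worked example

Generate a synthetic graph with one planted directional claim, then query
it:

```bash
claimtriage simulate --config gen.yaml --out-dir demo
# wrote graph to demo (11 planted evidence records)

claimtriage query \
  --subject "bazovilo karuseti pomelaki" --predicate CAUSES \
  --object "tivuneso halomeri kupatevo" \
  --kg-dir demo --out report.json
```

where `gen.yaml` plants 3 supporting + 1 reversal literature triples and
2 supporting / 1 reversal / 2 insufficient / 2 additional associations for
the claim (see `claimtriage simulate --help`). The report's aggregates are:

```
TRIPLE_LIT SUPPORTING   count=3 total=3.237209
TRIPLE_LIT REVERSAL     count=1 total=1.0
ASSOC      SUPPORTING   count=2 total=5.11634
ASSOC      REVERSAL     count=1 total=2.61807
ASSOC      INSUFFICIENT count=2 total=0.73492
ASSOC      ADDITIONAL   count=2 total=3.07443
```

Every planted record is recovered under its designated type. Counts are
item counts per cell; totals are summed evidence scores — e.g. the two
supporting associations average ≈ 2.6 because their standardized effects
sit well past the z(π) boundary (strength > 1) and their labels matched
exactly (mapping score 1). One supporting item in full:

```json
{"source_trait_id": "ukb-d-30001", "target_trait_id": "ukb-d-30003",
 "assoc_type": "MR_EVE_MR", "effect_size": -3.624, "standard_error": 0.406,
 "p_value": 4.3e-19, "mapping_score": 1.0,
 "strength_score": 2.713419, "evidence_score": 2.713419}
```

The same report can be rendered as a forest-plot payload
(`--forest-out`) or a network diagram payload (`--network-out`) with
mapping edges (claim term → ontology term → evidence entity) separated
from evidence edges. `claimtriage batch` processes a TSV of claims and
writes a per-claim summary table; `claimtriage validate` lints a graph
directory.

## Layout

| Module                       | Role                                              |
|------------------------------|---------------------------------------------------|
| `claimtriage.kg`             | graph store, validation, CSV/JSONL/OBO/GraphML IO |
| `claimtriage.encoder`        | encoder contract, trigram fallback, top-k search  |
| `claimtriage.harmonization`  | two-stage entity harmonization                    |
| `claimtriage.engine`         | rule-table classification, query orchestration    |
| `claimtriage.scoring`        | mapping / strength / evidence scores, aggregates  |
| `claimtriage.synthetic`      | seeded generator with planted ground truth        |
| `claimtriage.cli`            | `query`, `batch`, `simulate`, `validate` verbs    |
| `claimtriage.report`         | JSON report, forest-plot and network payloads     |

See `docs/methods.md` for the model, parameter defaults, and limitations.
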