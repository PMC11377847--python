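"""Structured query reports and their render targets.

An :class:`EvidenceReport` is the single output of a query: the claim, a
harmonization summary per side, every classified and scored evidence item
grouped by (evidence group, evidence type), the per-cell aggregates, and an
echo of the configuration that produced it.  It serializes to JSON with a
stable key order, so repeated runs on the same graph are byte-identical.

Two derived payloads serve downstream visualization: a forest-plot table of
the association items (effect, SE, P-value, trait labels, evidence type) and
a network diagram of the harmonized entities and evidence, with mapping
edges (claim term -> ontology term -> evidence entity) distinguished from
evidence edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from .engine import EvidenceGroup, EvidenceType
from .harmonization import HarmonizationConfig, HarmonizationResult
from .kg import ClaimTriple

SCHEMA_VERSION = "1.0"

__all__ = [
    "EvidenceReport",
    "NetworkPayload",
    "build_report",
    "render_network",
    "forest_plot_payload",
]

_SCORE_DECIMALS = 6


def _r(x: float) -> float:
    return round(float(x), _SCORE_DECIMALS)


@dataclass
class EvidenceReport:
    """JSON-serializable result of one claim query."""

    data: dict

    @property
    def claim(self) -> dict:
        return self.data["claim"]

    @property
    def status(self) -> str:
        return self.data["status"]

    @property
    def aggregates(self) -> list:
        return self.data["aggregates"]

    def items(self, group: str | EvidenceGroup, etype: str | EvidenceType) -> list:
        group = EvidenceGroup(group).value
        etype = EvidenceType(etype).value
        return self.data["evidence"][group][etype]

    def aggregate(self, group, etype) -> dict:
        group = EvidenceGroup(group).value
        etype = EvidenceType(etype).value
        for cell in self.data["aggregates"]:
            if cell["group"] == group and cell["type"] == etype:
                return cell
        raise KeyError((group, etype))

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.data, indent=indent, allow_nan=False)

    @classmethod
    def from_json(cls, text: str) -> "EvidenceReport":
        return cls(data=json.loads(text))

    def __eq__(self, other) -> bool:
        return isinstance(other, EvidenceReport) and self.data == other.data


def _side_summary(side) -> dict:
    return {
        "query_term": side.query_term,
        "candidates": [
            {
                "term_id": c.term_id,
                "label": c.label,
                "similarity": _r(c.similarity),
                "ic_score": _r(c.ic_score),
                "identity_score": _r(c.identity_score),
                "selected": c.selected,
            }
            for c in side.candidates
        ],
        "selected_terms": side.selected_term_ids,
        "fallback_used": side.fallback_used,
        "lit_terms": [
            {
                "id": m.entity.id,
                "label": m.entity.label,
                "ontology_term_id": m.ontology_term_id,
                "similarity": _r(m.similarity),
            }
            for m in side.lit_mappings
        ],
        "traits": [
            {
                "id": m.entity.id,
                "label": m.entity.label,
                "ontology_term_id": m.ontology_term_id,
                "similarity": _r(m.similarity),
            }
            for m in side.trait_mappings
        ],
    }


def _item_payload(scored) -> dict:
    c = scored.classified
    base = {
        "orientation": c.orientation.value,
        "subject_chain": [_r(s) for s in c.subject_chain],
        "object_chain": [_r(s) for s in c.object_chain],
        "mapping_score": _r(scored.mapping_score),
        "strength_score": _r(scored.strength_score),
        "evidence_score": _r(scored.evidence_score),
    }
    if c.group is EvidenceGroup.TRIPLE_LIT:
        base.update(
            {
                "subject_id": c.item.subject_id,
                "predicate": c.item.predicate.value,
                "object_id": c.item.object_id,
                "literature_ids": list(c.item.literature_ids),
                "n_literature": len(c.item.literature_ids),
            }
        )
    else:
        base.update(
            {
                "source_trait_id": c.item.source_trait_id,
                "target_trait_id": c.item.target_trait_id,
                "assoc_type": c.item.assoc_type.value,
                "effect_size": c.item.effect_size,
                "standard_error": c.item.standard_error,
                "p_value": c.item.p_value,
            }
        )
    return base


def build_report(
    claim: ClaimTriple,
    harm: HarmonizationResult,
    scored: Iterable,
    aggregates,
    harm_cfg: HarmonizationConfig,
    ev_cfg,
) -> EvidenceReport:
    evidence: dict = {
        g.value: {t.value: [] for t in EvidenceType} for g in EvidenceGroup
    }
    for item in scored:
        evidence[item.classified.group.value][item.classified.type.value].append(
            _item_payload(item)
        )
    data = {
        "schema_version": SCHEMA_VERSION,
        "claim": {
            "subject_term": claim.subject_term,
            "predicate": claim.predicate.value,
            "object_term": claim.object_term,
        },
        "status": "ok" if harm.has_mappings else "no mapped entities",
        "harmonization": {
            "subject": _side_summary(harm.subject),
            "object": _side_summary(harm.object),
        },
        "evidence": evidence,
        "aggregates": [
            {
                "group": g.value,
                "type": t.value,
                "count": count,
                "total_score": _r(total),
            }
            for g, t, count, total in aggregates.cells
        ],
        "config": {
            "harmonization": json.loads(harm_cfg.model_dump_json()),
            "evidence": {
                "p_threshold": ev_cfg.p_threshold,
                "directional_assoc_types": sorted(
                    t.value for t in ev_cfg.directional_assoc_types
                ),
                "non_directional_assoc_types": sorted(
                    t.value for t in ev_cfg.non_directional_assoc_types
                ),
                "additional_requires_p": ev_cfg.additional_requires_p,
            },
        },
    }
    return EvidenceReport(data=data)


def forest_plot_payload(report: EvidenceReport) -> list:
    """Rows for a forest plot of the association evidence items."""
    rows = []
    trait_labels = {}
    for side in ("subject", "object"):
        for trait in report.data["harmonization"][side]["traits"]:
            trait_labels[trait["id"]] = trait["label"]
    for etype in EvidenceType:
        for item in report.items(EvidenceGroup.ASSOC, etype):
            rows.append(
                {
                    "source_trait_id": item["source_trait_id"],
                    "source_trait_label": trait_labels.get(item["source_trait_id"], ""),
                    "target_trait_id": item["target_trait_id"],
                    "target_trait_label": trait_labels.get(item["target_trait_id"], ""),
                    "assoc_type": item["assoc_type"],
                    "effect_size": item["effect_size"],
                    "standard_error": item["standard_error"],
                    "p_value": item["p_value"],
                    "evidence_type": etype.value,
                    "evidence_score": item["evidence_score"],
                }
            )
    return rows


# -- network payload -------------------------------------------------------


@dataclass
class NetworkPayload:
    """Node/edge lists for a summary network diagram.

    Mapping edges (claim term -> ontology term, ontology term -> evidence
    entity) and evidence edges (triple/association links) partition the edge
    set; render mapping edges dashed and evidence edges solid.
    """

    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)

    def validate(self) -> None:
        ids = {n["id"] for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids in network payload")
        for e in self.edges:
            for endpoint in (e["source"], e["target"]):
                if endpoint not in ids:
                    raise ValueError(f"edge endpoint {endpoint!r} has no node")
            if e["kind"] not in ("mapping", "evidence"):
                raise ValueError(f"unknown edge kind {e['kind']!r}")


def render_network(report: EvidenceReport) -> NetworkPayload:
    """Build the entity/evidence network for one report."""
    payload = NetworkPayload()
    seen: set = set()

    def add_node(node_id, kind, label, size=1):
        if node_id not in seen:
            payload.nodes.append(
                {"id": node_id, "kind": kind, "label": label, "size": size}
            )
            seen.add(node_id)

    def add_edge(source, target, kind, weight):
        payload.edges.append(
            {"source": source, "target": target, "kind": kind, "weight": _r(weight)}
        )

    claim = report.claim
    subj_node, obj_node = "claim:subject", "claim:object"
    add_node(subj_node, "claim_term", claim["subject_term"])
    add_node(obj_node, "claim_term", claim["object_term"])

    for side, side_node in (("subject", subj_node), ("object", obj_node)):
        summary = report.data["harmonization"][side]
        selected = {
            c["term_id"]: c for c in summary["candidates"] if c["selected"]
        }
        for term_id, cand in selected.items():
            onto = f"ontology:{term_id}"
            add_node(onto, "ontology", cand["label"])
            add_edge(side_node, onto, "mapping", cand["similarity"])
        for kind, entries in (("lit_term", summary["lit_terms"]), ("trait", summary["traits"])):
            for entry in entries:
                node = f"{kind}:{entry['id']}"
                add_node(node, kind, entry["label"])
                add_edge(
                    f"ontology:{entry['ontology_term_id']}",
                    node,
                    "mapping",
                    entry["similarity"],
                )

    for etype in EvidenceType:
        for item in report.items(EvidenceGroup.TRIPLE_LIT, etype):
            triple_node = (
                f"triple:{item['subject_id']}|{item['predicate']}|{item['object_id']}"
            )
            add_node(
                triple_node,
                "triple",
                f"{item['subject_id']} {item['predicate']} {item['object_id']}",
                size=item["n_literature"],
            )
            for term in (item["subject_id"], item["object_id"]):
                add_edge(f"lit_term:{term}", triple_node, "evidence", item["evidence_score"])
            for art in item["literature_ids"]:
                lit_node = f"literature:{art}"
                add_node(lit_node, "literature", art)
                add_edge(triple_node, lit_node, "evidence", 1.0)
        for item in report.items(EvidenceGroup.ASSOC, etype):
            add_edge(
                f"trait:{item['source_trait_id']}",
                f"trait:{item['target_trait_id']}",
                "evidence",
                item["evidence_score"],
            )
    payload.validate()
    return payload
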