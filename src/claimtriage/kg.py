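"""In-memory knowledge graph of entities, ontology structure, and evidence records.

The graph holds three entity taxonomies:

* ``ONTOLOGY`` — terms of a hierarchical ontology (EFO-style) connected by
  is-a edges forming a DAG; the harmonization layer uses these as the bridge
  between a claim's free-text terms and the evidence vocabularies.
* ``LIT_TERM`` — controlled-vocabulary terms (UMLS-style) that appear as
  subjects/objects of literature-derived semantic triples.
* ``TRAIT`` — GWAS trait entities that appear as endpoints of statistical
  association records (Mendelian randomization, genetic correlation,
  polygenic score).

Evidence comes in two record kinds: literature triples (subject PREDICATE
object, backed by one or more source articles) and trait-pair associations
(effect size, standard error, P-value).  All loaders validate referential
integrity and ontology acyclicity up front; the store is append-only after
construction, so those invariants hold for its lifetime.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "Taxonomy",
    "Predicate",
    "AssociationType",
    "DIRECTIONAL_PREDICATES",
    "NON_DIRECTIONAL_PREDICATES",
    "Entity",
    "OntologyEdge",
    "ClaimTriple",
    "TripleEvidenceRecord",
    "LiteratureRecord",
    "AssociationRecord",
    "KnowledgeGraph",
    "GraphValidationError",
    "GraphLookupError",
    "load_graph",
    "load_graph_dir",
    "save_graph",
    "triples_matching",
    "associations_between",
    "ontology_descendants",
]


class GraphValidationError(ValueError):
    """A file or record violates the graph schema or an invariant."""


class GraphLookupError(KeyError):
    """A referenced entity or record does not exist in the graph."""


class Taxonomy(str, enum.Enum):
    ONTOLOGY = "ONTOLOGY"
    LIT_TERM = "LIT_TERM"
    TRAIT = "TRAIT"


class Predicate(str, enum.Enum):
    AFFECTS = "AFFECTS"
    CAUSES = "CAUSES"
    PRODUCES = "PRODUCES"
    TREATS = "TREATS"
    ASSOCIATED_WITH = "ASSOCIATED_WITH"
    COEXISTS_WITH = "COEXISTS_WITH"
    INTERACTS_WITH = "INTERACTS_WITH"


#: Predicates whose claims assert a direction (cause -> effect).
DIRECTIONAL_PREDICATES = frozenset(
    {Predicate.AFFECTS, Predicate.CAUSES, Predicate.PRODUCES, Predicate.TREATS}
)
#: Predicates whose claims are symmetric in subject and object.
NON_DIRECTIONAL_PREDICATES = frozenset(
    {Predicate.ASSOCIATED_WITH, Predicate.COEXISTS_WITH, Predicate.INTERACTS_WITH}
)


class AssociationType(str, enum.Enum):
    MR_EVE_MR = "MR_EVE_MR"
    GEN_COR = "GEN_COR"
    PRS = "PRS"


def coerce_predicate(value: "str | Predicate") -> Predicate:
    """Coerce a string to a :class:`Predicate`, with a helpful error."""
    if isinstance(value, Predicate):
        return value
    try:
        return Predicate(str(value))
    except ValueError:
        legal = ", ".join(p.value for p in Predicate)
        raise GraphValidationError(
            f"unknown predicate {value!r}; legal predicates: {legal}"
        ) from None


@dataclass(frozen=True)
class Entity:
    """A member of one of the three taxonomies.

    ``semantic_types`` carries short UMLS-style type codes (``dsyn``,
    ``gngm`` ...) for literature terms; it may be empty for other
    taxonomies.  ``synonyms`` is an optional list of alternative labels used
    by similarity retrieval when enabled.
    """

    taxonomy: Taxonomy
    id: str
    label: str
    semantic_types: frozenset = frozenset()
    synonyms: tuple = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("entity id must be non-empty")
        if not self.label:
            raise GraphValidationError(f"entity {self.id!r}: label must be non-empty")


@dataclass(frozen=True)
class OntologyEdge:
    """A single is-a link: ``child_id`` is-a ``parent_id``."""

    child_id: str
    parent_id: str


@dataclass(frozen=True)
class ClaimTriple:
    """The query: a subject term, a predicate, and an object term."""

    subject_term: str
    predicate: Predicate
    object_term: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicate", coerce_predicate(self.predicate))
        if not self.subject_term or not self.object_term:
            raise GraphValidationError("claim subject and object terms must be non-empty")

    def swapped(self) -> "ClaimTriple":
        return ClaimTriple(self.object_term, self.predicate, self.subject_term)


@dataclass(frozen=True)
class TripleEvidenceRecord:
    """A literature-derived semantic triple and its source articles."""

    subject_id: str
    predicate: Predicate
    object_id: str
    literature_ids: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicate", coerce_predicate(self.predicate))
        object.__setattr__(self, "literature_ids", tuple(self.literature_ids))
        if len(self.literature_ids) < 1:
            raise GraphValidationError(
                f"triple ({self.subject_id}, {self.predicate.value}, {self.object_id}) "
                "must reference at least one literature item"
            )

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.predicate.value, self.object_id)


@dataclass(frozen=True)
class LiteratureRecord:
    article_id: str
    title: str = ""
    context_sentence: str = ""


@dataclass(frozen=True)
class AssociationRecord:
    """A trait-pair statistical association.

    ``directional`` defaults from the association type (MR estimates carry a
    direction; genetic correlations and PRS associations do not) but may be
    overridden per record by the data source.
    """

    source_trait_id: str
    target_trait_id: str
    assoc_type: AssociationType
    effect_size: float
    standard_error: float
    p_value: float
    directional: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assoc_type", AssociationType(self.assoc_type))
        if self.directional is None:
            object.__setattr__(
                self, "directional", self.assoc_type == AssociationType.MR_EVE_MR
            )
        if not (self.standard_error > 0):
            raise GraphValidationError(
                f"association ({self.source_trait_id}, {self.target_trait_id}): "
                f"standard_error must be > 0, got {self.standard_error}"
            )
        if not (0 < self.p_value <= 1):
            raise GraphValidationError(
                f"association ({self.source_trait_id}, {self.target_trait_id}): "
                f"p_value must be in (0, 1], got {self.p_value}"
            )
        for x, name in ((self.effect_size, "effect_size"),):
            if not math.isfinite(x):
                raise GraphValidationError(f"association {name} must be finite")

    @property
    def key(self) -> tuple:
        return (self.source_trait_id, self.target_trait_id, self.assoc_type.value)


class KnowledgeGraph:
    """Validated, indexed, append-only store of entities and evidence.

    Construction checks every foreign key, rejects duplicate entity ids
    within a taxonomy, merges literature triples that share the same
    (subject, predicate, object) key, and verifies that the ontology edge
    set is acyclic.
    """

    def __init__(
        self,
        entities: Iterable[Entity],
        ontology_edges: Iterable[OntologyEdge] = (),
        triples: Iterable[TripleEvidenceRecord] = (),
        associations: Iterable[AssociationRecord] = (),
        literature: Iterable[LiteratureRecord] = (),
    ) -> None:
        self._entities: dict[tuple, Entity] = {}
        for ent in entities:
            k = (ent.taxonomy, ent.id)
            if k in self._entities:
                raise GraphValidationError(
                    f"duplicate entity id {ent.id!r} in taxonomy {ent.taxonomy.value}"
                )
            self._entities[k] = ent

        self._literature: dict[str, LiteratureRecord] = {}
        for lit in literature:
            if lit.article_id in self._literature:
                raise GraphValidationError(f"duplicate article id {lit.article_id!r}")
            self._literature[lit.article_id] = lit

        # ontology DAG: edges run child -> parent
        self._ontology = nx.DiGraph()
        for k, ent in self._entities.items():
            if ent.taxonomy is Taxonomy.ONTOLOGY:
                self._ontology.add_node(ent.id)
        self._ontology_edges: list[OntologyEdge] = []
        for edge in ontology_edges:
            for term_id, role in ((edge.child_id, "child"), (edge.parent_id, "parent")):
                if (Taxonomy.ONTOLOGY, term_id) not in self._entities:
                    raise GraphValidationError(
                        f"ontology edge {role} {term_id!r} is not an ONTOLOGY entity"
                    )
            self._ontology.add_edge(edge.child_id, edge.parent_id)
            self._ontology_edges.append(edge)
        try:
            cycle = nx.find_cycle(self._ontology)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise GraphValidationError(f"ontology is-a edges contain a cycle: {path}")

        self._triples: dict[tuple, TripleEvidenceRecord] = {}
        self._triples_by_subject: dict[tuple, list] = {}
        self._triples_by_object: dict[tuple, list] = {}
        for rec in triples:
            for term_id, fld in ((rec.subject_id, "subject_id"), (rec.object_id, "object_id")):
                if (Taxonomy.LIT_TERM, term_id) not in self._entities:
                    raise GraphValidationError(
                        f"triple {rec.key}: {fld} {term_id!r} is not a LIT_TERM entity"
                    )
            for art in rec.literature_ids:
                if art not in self._literature:
                    raise GraphValidationError(
                        f"triple {rec.key}: unknown literature id {art!r}"
                    )
            if rec.key in self._triples:
                # same (s, p, o) seen twice: merge the article lists
                old = self._triples[rec.key]
                merged = tuple(sorted(set(old.literature_ids) | set(rec.literature_ids)))
                rec = TripleEvidenceRecord(
                    rec.subject_id, rec.predicate, rec.object_id, merged
                )
            self._triples[rec.key] = rec
        for rec in self._triples.values():
            self._triples_by_subject.setdefault(
                (rec.subject_id, rec.predicate), []
            ).append(rec)
            self._triples_by_object.setdefault(
                (rec.object_id, rec.predicate), []
            ).append(rec)

        self._associations: list[AssociationRecord] = []
        self._assoc_by_source: dict[str, list] = {}
        self._assoc_by_target: dict[str, list] = {}
        seen_assoc: set = set()
        for rec in associations:
            for term_id, fld in (
                (rec.source_trait_id, "source_trait_id"),
                (rec.target_trait_id, "target_trait_id"),
            ):
                if (Taxonomy.TRAIT, term_id) not in self._entities:
                    raise GraphValidationError(
                        f"association {rec.key}: {fld} {term_id!r} is not a TRAIT entity"
                    )
            if rec.key in seen_assoc:
                raise GraphValidationError(f"duplicate association record {rec.key}")
            seen_assoc.add(rec.key)
            self._associations.append(rec)
            self._assoc_by_source.setdefault(rec.source_trait_id, []).append(rec)
            self._assoc_by_target.setdefault(rec.target_trait_id, []).append(rec)

    # -- entity access -----------------------------------------------------

    def entity(self, taxonomy: Taxonomy, entity_id: str) -> Entity:
        try:
            return self._entities[(taxonomy, entity_id)]
        except KeyError:
            raise GraphLookupError(
                f"no {taxonomy.value} entity with id {entity_id!r}"
            ) from None

    def has_entity(self, taxonomy: Taxonomy, entity_id: str) -> bool:
        return (taxonomy, entity_id) in self._entities

    def entities(self, taxonomy: Taxonomy | None = None) -> list:
        out = [
            e
            for (tax, _), e in self._entities.items()
            if taxonomy is None or tax is taxonomy
        ]
        return sorted(out, key=lambda e: (e.taxonomy.value, e.id))

    def catalog(self, taxonomy: Taxonomy) -> list:
        """(id, label) pairs of a taxonomy, sorted by id (retrieval input)."""
        return [(e.id, e.label) for e in self.entities(taxonomy)]

    @property
    def ontology_edges(self) -> list:
        return sorted(self._ontology_edges, key=lambda e: (e.child_id, e.parent_id))

    @property
    def triples(self) -> list:
        return sorted(self._triples.values(), key=lambda r: r.key)

    @property
    def associations(self) -> list:
        return sorted(self._associations, key=lambda r: r.key)

    @property
    def literature(self) -> list:
        return sorted(self._literature.values(), key=lambda r: r.article_id)

    def literature_record(self, article_id: str) -> LiteratureRecord:
        try:
            return self._literature[article_id]
        except KeyError:
            raise GraphLookupError(f"no literature record {article_id!r}") from None

    @property
    def n_ontology_terms(self) -> int:
        return self._ontology.number_of_nodes()

    # -- queries -----------------------------------------------------------

    def ontology_descendants(self, term_id: str) -> set:
        """All terms reachable from below via is-a chains, excluding the term."""
        if (Taxonomy.ONTOLOGY, term_id) not in self._entities:
            raise GraphLookupError(f"no ONTOLOGY entity with id {term_id!r}")
        # edges run child -> parent, so graph-ancestors are ontology descendants
        return set(nx.ancestors(self._ontology, term_id))

    def ontology_roots(self) -> list:
        return sorted(
            n for n in self._ontology.nodes if self._ontology.out_degree(n) == 0
        )

    def triples_matching(
        self,
        subject_ids: Iterable[str],
        predicate: Predicate,
        object_ids: Iterable[str],
    ) -> list:
        predicate = coerce_predicate(predicate)
        object_ids = set(object_ids)
        out = []
        for sid in set(subject_ids):
            for rec in self._triples_by_subject.get((sid, predicate), ()):
                if rec.object_id in object_ids:
                    out.append(rec)
        return sorted(out, key=lambda r: (r.subject_id, r.object_id))

    def associations_between(
        self,
        source_ids: Iterable[str],
        target_ids: Iterable[str],
        assoc_types: Iterable[AssociationType] = frozenset(AssociationType),
    ) -> list:
        source_ids, target_ids = set(source_ids), set(target_ids)
        assoc_types = {AssociationType(t) for t in assoc_types}
        out: dict[tuple, AssociationRecord] = {}
        for sid in source_ids:
            for rec in self._assoc_by_source.get(sid, ()):
                if rec.assoc_type in assoc_types and rec.target_trait_id in target_ids:
                    out[rec.key] = rec
        # non-directional records match in either orientation
        for sid in target_ids:
            for rec in self._assoc_by_source.get(sid, ()):
                if (
                    not rec.directional
                    and rec.assoc_type in assoc_types
                    and rec.target_trait_id in source_ids
                ):
                    out[rec.key] = rec
        return sorted(out.values(), key=lambda r: r.key)


# -- module-level operation aliases ---------------------------------------


def triples_matching(kg, subject_ids, predicate, object_ids):
    return kg.triples_matching(subject_ids, predicate, object_ids)


def associations_between(kg, source_ids, target_ids, assoc_types=frozenset(AssociationType)):
    return kg.associations_between(source_ids, target_ids, assoc_types)


def ontology_descendants(kg, term_id):
    return kg.ontology_descendants(term_id)


# -- on-disk formats -------------------------------------------------------
#
# nodes:        CSV (taxonomy, id, label, semantic_types, synonyms) with the
#               multi-valued columns semicolon-joined
# ontology:     OBO (is_a subset) or two-column CSV (child_id, parent_id)
# triples:      JSON-lines, literature_ids as an array
# literature:   JSON-lines
# associations: CSV


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise GraphValidationError(f"{path}: missing column(s) {missing}")


def _split_multi(cell: str) -> tuple:
    return tuple(s for s in str(cell).split(";") if s) if cell else ()


def read_nodes_csv(path: "str | Path") -> list:
    path = Path(path)
    df = _read_csv(path)
    _require_columns(df, ["taxonomy", "id", "label"], path)
    entities = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            taxonomy = Taxonomy(row.taxonomy)
        except ValueError:
            raise GraphValidationError(
                f"{path} row {i}: field 'taxonomy' has unknown value {row.taxonomy!r}"
            ) from None
        if not row.id:
            raise GraphValidationError(f"{path} row {i}: field 'id' is empty")
        if not row.label:
            raise GraphValidationError(f"{path} row {i}: field 'label' is empty")
        entities.append(
            Entity(
                taxonomy=taxonomy,
                id=row.id,
                label=row.label,
                semantic_types=frozenset(_split_multi(getattr(row, "semantic_types", ""))),
                synonyms=_split_multi(getattr(row, "synonyms", "")),
            )
        )
    return entities


def read_ontology_file(path: "str | Path") -> tuple:
    """Read an ontology as (entities, edges).

    OBO input (``.obo``) defines both the terms and their is_a links; CSV
    input is a bare (child_id, parent_id) edge table and contributes no
    entities (labels must come from the node table).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() == ".obo":
        graph = obonet.read_obo(str(path))
        entities = []
        for term_id, data in sorted(graph.nodes(data=True)):
            label = data.get("name") or ""
            if not label:
                raise GraphValidationError(f"{path}: term {term_id} has no name")
            synonyms = tuple(
                s.split('"')[1] for s in data.get("synonym", ()) if '"' in s
            )
            entities.append(
                Entity(Taxonomy.ONTOLOGY, term_id, label, synonyms=synonyms)
            )
        edges = [
            OntologyEdge(child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        return entities, sorted(edges, key=lambda e: (e.child_id, e.parent_id))
    df = _read_csv(path)
    _require_columns(df, ["child_id", "parent_id"], path)
    edges = [
        OntologyEdge(row.child_id, row.parent_id)
        for row in df.itertuples(index=False)
    ]
    return [], edges


def read_triples_jsonl(path: "str | Path") -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise GraphValidationError(f"{path} row {i}: invalid JSON ({exc})") from None
            for fld in ("subject_id", "predicate", "object_id", "literature_ids"):
                if fld not in obj:
                    raise GraphValidationError(f"{path} row {i}: field {fld!r} missing")
            records.append(
                TripleEvidenceRecord(
                    subject_id=obj["subject_id"],
                    predicate=obj["predicate"],
                    object_id=obj["object_id"],
                    literature_ids=tuple(obj["literature_ids"]),
                )
            )
    return records


def read_literature_jsonl(path: "str | Path") -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "article_id" not in obj:
                raise GraphValidationError(f"{path} row {i}: field 'article_id' missing")
            records.append(
                LiteratureRecord(
                    article_id=obj["article_id"],
                    title=obj.get("title", ""),
                    context_sentence=obj.get("context_sentence", ""),
                )
            )
    return records


def read_associations_csv(path: "str | Path") -> list:
    path = Path(path)
    df = _read_csv(path)
    _require_columns(
        df,
        ["source_trait_id", "target_trait_id", "assoc_type", "effect_size",
         "standard_error", "p_value"],
        path,
    )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        for fld in ("effect_size", "standard_error", "p_value"):
            try:
                vals[fld] = float(getattr(row, fld))
            except ValueError:
                raise GraphValidationError(
                    f"{path} row {i}: field {fld!r} is not numeric "
                    f"({getattr(row, fld)!r})"
                ) from None
        try:
            assoc_type = AssociationType(row.assoc_type)
        except ValueError:
            raise GraphValidationError(
                f"{path} row {i}: field 'assoc_type' has unknown value {row.assoc_type!r}"
            ) from None
        directional = None
        if hasattr(row, "directional") and str(row.directional) != "":
            directional = str(row.directional).lower() in ("true", "1", "yes")
        try:
            records.append(
                AssociationRecord(
                    source_trait_id=row.source_trait_id,
                    target_trait_id=row.target_trait_id,
                    assoc_type=assoc_type,
                    directional=directional,
                    **vals,
                )
            )
        except GraphValidationError as exc:
            raise GraphValidationError(f"{path} row {i}: {exc}") from None
    return records


def load_graph(
    node_path: "str | Path",
    ontology_path: "str | Path | None" = None,
    triple_path: "str | Path | None" = None,
    association_path: "str | Path | None" = None,
    literature_path: "str | Path | None" = None,
) -> KnowledgeGraph:
    """Load and validate a knowledge graph from its component tables."""
    entities = read_nodes_csv(node_path)
    edges: list = []
    if ontology_path is not None:
        obo_entities, edges = read_ontology_file(ontology_path)
        entities = entities + obo_entities
    literature = read_literature_jsonl(literature_path) if literature_path else []
    triples = read_triples_jsonl(triple_path) if triple_path else []
    associations = read_associations_csv(association_path) if association_path else []
    return KnowledgeGraph(entities, edges, triples, associations, literature)


#: Conventional file names inside a graph directory.
GRAPH_FILES = {
    "nodes": "nodes.csv",
    "ontology": "ontology.csv",
    "ontology_obo": "ontology.obo",
    "triples": "triples.jsonl",
    "literature": "literature.jsonl",
    "associations": "associations.csv",
}


def load_graph_dir(directory: "str | Path") -> KnowledgeGraph:
    """Load a graph from a directory using the conventional file names."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    ontology = directory / GRAPH_FILES["ontology"]
    if not ontology.exists():
        ontology = directory / GRAPH_FILES["ontology_obo"]

    def opt(name: str):
        p = directory / GRAPH_FILES[name]
        return p if p.exists() else None

    return load_graph(
        node_path=directory / GRAPH_FILES["nodes"],
        ontology_path=ontology if ontology.exists() else None,
        triple_path=opt("triples"),
        association_path=opt("associations"),
        literature_path=opt("literature"),
    )


def save_graph(kg: KnowledgeGraph, directory: "str | Path") -> None:
    """Write a graph back to disk in the conventional dialects (round-trips)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            {
                "taxonomy": e.taxonomy.value,
                "id": e.id,
                "label": e.label,
                "semantic_types": ";".join(sorted(e.semantic_types)),
                "synonyms": ";".join(e.synonyms),
            }
            for e in kg.entities()
        ],
        columns=["taxonomy", "id", "label", "semantic_types", "synonyms"],
    )
    nodes.to_csv(directory / GRAPH_FILES["nodes"], index=False)
    pd.DataFrame(
        [{"child_id": e.child_id, "parent_id": e.parent_id} for e in kg.ontology_edges],
        columns=["child_id", "parent_id"],
    ).to_csv(directory / GRAPH_FILES["ontology"], index=False)
    with open(directory / GRAPH_FILES["triples"], "w", encoding="utf-8") as fh:
        for rec in kg.triples:
            fh.write(
                json.dumps(
                    {
                        "subject_id": rec.subject_id,
                        "predicate": rec.predicate.value,
                        "object_id": rec.object_id,
                        "literature_ids": list(rec.literature_ids),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    with open(directory / GRAPH_FILES["literature"], "w", encoding="utf-8") as fh:
        for lit in kg.literature:
            fh.write(
                json.dumps(
                    {
                        "article_id": lit.article_id,
                        "title": lit.title,
                        "context_sentence": lit.context_sentence,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    pd.DataFrame(
        [
            {
                "source_trait_id": r.source_trait_id,
                "target_trait_id": r.target_trait_id,
                "assoc_type": r.assoc_type.value,
                "effect_size": repr(r.effect_size),
                "standard_error": repr(r.standard_error),
                "p_value": repr(r.p_value),
                "directional": str(r.directional).lower(),
            }
            for r in kg.associations
        ],
        columns=["source_trait_id", "target_trait_id", "assoc_type",
                 "effect_size", "standard_error", "p_value", "directional"],
    ).to_csv(directory / GRAPH_FILES["associations"], index=False)


def to_networkx(kg: KnowledgeGraph) -> nx.MultiDiGraph:
    """Merged view of the whole graph for export (e.g. GraphML)."""
    g = nx.MultiDiGraph()
    for e in kg.entities():
        g.add_node(
            f"{e.taxonomy.value}:{e.id}",
            taxonomy=e.taxonomy.value,
            label=e.label,
            semantic_types=";".join(sorted(e.semantic_types)),
        )
    for edge in kg.ontology_edges:
        g.add_edge(
            f"ONTOLOGY:{edge.child_id}", f"ONTOLOGY:{edge.parent_id}", kind="is_a"
        )
    for rec in kg.triples:
        g.add_edge(
            f"LIT_TERM:{rec.subject_id}",
            f"LIT_TERM:{rec.object_id}",
            kind=rec.predicate.value,
            n_literature=len(rec.literature_ids),
        )
    for rec in kg.associations:
        g.add_edge(
            f"TRAIT:{rec.source_trait_id}",
            f"TRAIT:{rec.target_trait_id}",
            kind=rec.assoc_type.value,
            effect_size=rec.effect_size,
            standard_error=rec.standard_error,
            p_value=rec.p_value,
        )
    return g


def save_graphml(kg: KnowledgeGraph, path: "str | Path") -> None:
    nx.write_graphml(to_networkx(kg), str(path))
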