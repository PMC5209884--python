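"""Turtle serialization of instance graphs.

Every entity becomes a subject in a project namespace; its typed fields
become datatype properties and the modelled relations (``instance_of``,
``part_of``, ``is_about``, ``has_probability_value``, ...) become object
properties from a fixed, closed vocabulary.  The local names of the
input/output/value/aboutness properties follow the IAO/OBI naming style,
but all IRIs are minted in the project namespace: nothing here depends on
live ontology imports.

Output is deterministic: subjects, predicates and objects are sorted, and
probabilities are written as decimal literals with 12 significant digits.
Parsing is done with rdflib and is strict — any predicate outside the
vocabulary is an error, so a round-trip is guaranteed to stay inside the
model.
"""

from __future__ import annotations

import decimal
import json
from typing import Union
from urllib.parse import quote, unquote

import rdflib
from rdflib.namespace import RDF

from .model import (
    Computation,
    ContingencyTable,
    DiseaseClass,
    Disposition,
    DispositionClass,
    IPEstimate,
    InstanceGraph,
    IntegrityError,
    LITERAL_RELATIONS,
    ModelError,
    PersonRecord,
    Population,
    RELATIONS,
    Sample,
    TestClass,
    TestProcess,
    TestsExecution,
    VocabularyError,
)

__all__ = ["BDXO_NS", "to_turtle", "from_turtle"]

BDXO_NS = "https://w3id.org/bdxo#"

# field name -> codec; "opt_*" fields are omitted when None
_SCHEMAS: dict[str, tuple[type, dict[str, str]]] = {
    "DiseaseClass": (DiseaseClass, {"label": "str"}),
    "TestClass": (
        TestClass,
        {"label": "str", "role": "str", "parent_id": "opt_str", "target_disease": "opt_str"},
    ),
    "PersonRecord": (PersonRecord, {"subgroup": "str", "diseased": "bool", "response_prob": "json"}),
    "Population": (Population, {"parent_id": "opt_str", "member_ids": "ref_list"}),
    "Sample": (Sample, {"population_id": "str", "member_ids": "str_list"}),
    "TestProcess": (TestProcess, {"test_class": "str", "person_id": "str", "result": "str"}),
    "TestsExecution": (
        TestsExecution,
        {
            "sample_id": "str",
            "index_class": "str",
            "reference_class": "str",
            "process_ids": "ref_list",
        },
    ),
    "ContingencyTable": (
        ContingencyTable,
        {"tp": "int", "fp": "int", "fn": "int", "tn": "int", "source_execution": "opt_str"},
    ),
    "Disposition": (
        Disposition,
        {
            "bearer_id": "str",
            "kind": "str",
            "disease": "str",
            "index_class": "opt_str",
            "trigger_descriptor": "str",
            "realization_descriptor": "str",
            "probability": "float",
        },
    ),
    "DispositionClass": (
        DispositionClass,
        {"kind": "str", "index_class": "str", "disease": "str"},
    ),
    "IPEstimate": (
        IPEstimate,
        {
            "kind": "str",
            "value": "float",
            "n_denominator": "int",
            "about": "opt_str",
            "ci_low": "opt_float",
            "ci_high": "opt_float",
            "inputs": "str_list",
            "method": "str",
        },
    ),
    "Computation": (Computation, {"method": "str"}),
}

# fields whose serialized value is a list of ids of nodes stored elsewhere
_REF_LIST_SOURCES = {
    "Population": ("member_ids", "members"),
    "TestsExecution": ("process_ids", "processes"),
}

_TYPE_BY_CLASS = {cls: name for name, (cls, _) in _SCHEMAS.items()}
_FIELD_NAMES = {field for _, fields in _SCHEMAS.values() for field in fields}


def _node_iri(node_id: str) -> str:
    return f"<{BDXO_NS}{quote(node_id, safe='')}>"


def _decimal_literal(value: float) -> str:
    text = f"{value:.12g}"
    if "e" in text or "E" in text:
        text = format(decimal.Decimal(text), "f")
    return f'"{text}"^^xsd:decimal'


def _string_literal(value: str) -> str:
    return json.dumps(value)  # JSON escaping is valid Turtle string escaping


def _field_value(node, name: str, codec: str) -> Union[str, None]:
    if codec == "ref_list":
        type_name = _TYPE_BY_CLASS[type(node)]
        _, attr = _REF_LIST_SOURCES[type_name]
        return _string_literal(json.dumps([child.id for child in getattr(node, attr)]))
    raw = getattr(node, name)
    if raw is None:
        if codec.startswith("opt_"):
            return None
        raise ModelError(f"field {name!r} of {node.id!r} is unexpectedly None")
    if codec in ("str", "opt_str"):
        return _string_literal(raw)
    if codec == "int":
        return str(int(raw))
    if codec in ("float", "opt_float"):
        return _decimal_literal(float(raw))
    if codec == "bool":
        return "true" if raw else "false"
    if codec == "json":
        return _string_literal(json.dumps(raw, sort_keys=True))
    if codec == "str_list":
        return _string_literal(json.dumps(list(raw)))
    raise ModelError(f"unknown codec {codec!r}")  # pragma: no cover


def to_turtle(graph: InstanceGraph) -> str:
    """Serialize a *valid* instance graph to deterministic Turtle."""
    from .model import validate_instance_graph

    report = validate_instance_graph(graph)
    if not report.ok:
        details = "; ".join(str(v) for v in report)
        raise ModelError(f"refusing to serialize an invalid graph: {details}")

    statements: dict[str, list[tuple[str, str]]] = {}
    for node in graph.nodes.values():
        type_name = _TYPE_BY_CLASS.get(type(node))
        if type_name is None:
            raise VocabularyError(f"node {node.id!r} has unserializable type {type(node).__name__}")
        subject = _node_iri(node.id)
        rows = statements.setdefault(subject, [])
        rows.append(("a", f"bdxo:{type_name}"))
        for field_name, codec in _SCHEMAS[type_name][1].items():
            rendered = _field_value(node, field_name, codec)
            if rendered is not None:
                rows.append((f"bdxo:{field_name}", rendered))
    for s, relation, o in graph.edges:
        if relation not in RELATIONS:
            raise VocabularyError(f"relation {relation!r} is outside the closed vocabulary")
        rendered = _decimal_literal(float(o)) if relation in LITERAL_RELATIONS else _node_iri(str(o))
        statements.setdefault(_node_iri(s), []).append((f"bdxo:{relation}", rendered))

    lines = [
        f"@prefix bdxo: <{BDXO_NS}> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
    ]
    for subject in sorted(statements):
        rows = sorted(set(statements[subject]))
        lines.append(subject)
        for i, (predicate, obj) in enumerate(rows):
            terminator = " ." if i == len(rows) - 1 else " ;"
            lines.append(f"    {predicate} {obj}{terminator}")
        lines.append("")
    return "\n".join(lines)


def _local_name(iri: str) -> str:
    if not iri.startswith(BDXO_NS):
        raise VocabularyError(f"IRI {iri!r} is outside the project namespace")
    return unquote(iri[len(BDXO_NS) :])


def from_turtle(document: str) -> InstanceGraph:
    """Parse Turtle (restricted to the project vocabulary) into a graph."""
    rdf = rdflib.Graph()
    try:
        rdf.parse(data=document, format="turtle")
    except Exception as exc:
        raise ModelError(f"malformed Turtle document: {exc}") from exc

    node_types: dict[str, str] = {}
    node_fields: dict[str, dict[str, object]] = {}
    edges: list[tuple[str, str, Union[str, float]]] = []
    foreign: set[str] = set()

    for s, p, o in rdf:
        subject = _local_name(str(s))
        if p == RDF.type:
            type_name = _local_name(str(o))
            if type_name not in _SCHEMAS:
                foreign.add(str(o))
                continue
            node_types[subject] = type_name
        elif str(p).startswith(BDXO_NS):
            predicate = _local_name(str(p))
            if predicate in RELATIONS:
                if predicate in LITERAL_RELATIONS:
                    edges.append((subject, predicate, float(o.toPython())))
                else:
                    edges.append((subject, predicate, _local_name(str(o))))
            elif predicate in _FIELD_NAMES:
                node_fields.setdefault(subject, {})[predicate] = o.toPython()
            else:
                foreign.add(str(p))
        else:
            foreign.add(str(p))
    if foreign:
        raise VocabularyError(f"predicates/types outside the vocabulary: {sorted(foreign)}")

    entities: dict[str, object] = {}
    pending_refs: list[tuple[str, str, list[str]]] = []  # (node id, attr, child ids)
    for node_id, type_name in node_types.items():
        cls, schema = _SCHEMAS[type_name]
        kwargs: dict[str, object] = {"id": node_id}
        raw = node_fields.get(node_id, {})
        for field_name, codec in schema.items():
            if field_name not in raw:
                if codec.startswith("opt_") or codec == "ref_list":
                    continue
                raise IntegrityError(f"node {node_id!r} is missing field {field_name!r}")
            value = raw[field_name]
            if codec == "ref_list":
                _, attr = _REF_LIST_SOURCES[type_name]
                pending_refs.append((node_id, attr, json.loads(str(value))))
                continue
            if codec in ("str", "opt_str"):
                kwargs[field_name] = str(value)
            elif codec == "int":
                kwargs[field_name] = int(value)
            elif codec in ("float", "opt_float"):
                kwargs[field_name] = float(value)
            elif codec == "bool":
                kwargs[field_name] = bool(value)
            elif codec in ("json", "str_list"):
                kwargs[field_name] = json.loads(str(value))
        entities[node_id] = cls(**kwargs)

    for node_id, attr, child_ids in pending_refs:
        children = []
        for child_id in child_ids:
            child = entities.get(child_id)
            if child is None:
                raise IntegrityError(
                    f"node {node_id!r} references {child_id!r}, absent from the document"
                )
            children.append(child)
        setattr(entities[node_id], attr, children)

    graph = InstanceGraph()
    for entity in entities.values():
        graph.add_node(entity)
    for s, relation, o in sorted(edges, key=lambda e: (e[0], e[1], str(e[2]))):
        graph.add_edge(s, relation, o)
    return graph
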