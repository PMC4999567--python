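"""Declarative domain-ontology model.

A :class:`DomainOntology` captures the structural knowledge a research team
holds about its domain -- which entities exist (e.g. ``Patient`` and
``Aneurysm``), which typed attributes each entity carries, how categorical
concepts are organized into hierarchies (as in the ICD-10 catalog), which
validation rules the data must satisfy, and which derived variables are
computed from the raw records.  Every other module of the package takes its
structural metadata from this one object, so that preprocessing, distance
calculation and model screening need no per-dataset code.

The on-disk representation is a versioned YAML document; see
``data/aneurysm_registry.ontology.yaml`` for the shipped example.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import DanglingReferenceError, SchemaError, UnknownConceptError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ATTRIBUTE_KINDS = ("numeric", "categorical", "hierarchical", "boolean")

#: truthy / falsy spellings accepted for boolean attributes in CSV records
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


# ---------------------------------------------------------------------------
# Concept hierarchies
# ---------------------------------------------------------------------------


@dataclass
class ConceptNode:
    """One concept in a rooted hierarchy (e.g. one vascular location)."""

    id: str
    label: str
    parent: Optional["ConceptNode"] = None
    depth: int = 0
    children: list["ConceptNode"] = field(default_factory=list, repr=False, compare=False)

    def ancestors_or_self(self) -> list["ConceptNode"]:
        """Path from the root down to this node (inclusive)."""
        path: list[ConceptNode] = []
        node: Optional[ConceptNode] = self
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def is_leaf(self) -> bool:
        return not self.children


class ConceptHierarchy:
    """A rooted tree of categorical concepts with unique ids.

    Depths are assigned on construction: the root has depth 0 and every
    child is one deeper than its parent.
    """

    def __init__(self, name: str, root: ConceptNode):
        self.name = name
        self.root = root
        self._index: dict[str, ConceptNode] = {}
        self._link(root, None, 0)

    def _link(self, node: ConceptNode, parent: Optional[ConceptNode], depth: int) -> None:
        if node.id in self._index:
            raise SchemaError(
                f"hierarchy {self.name!r}: duplicate concept id {node.id!r}"
            )
        node.parent = parent
        node.depth = depth
        self._index[node.id] = node
        for child in node.children:
            self._link(child, node, depth + 1)

    # -- queries ------------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def node(self, concept_id: str) -> ConceptNode:
        try:
            return self._index[concept_id]
        except KeyError:
            raise UnknownConceptError(
                f"concept {concept_id!r} not in hierarchy {self.name!r}"
            ) from None

    def depth(self, concept_id: str) -> int:
        return self.node(concept_id).depth

    def leaves(self) -> list[ConceptNode]:
        """Leaf concepts in stable pre-order (used for one-hot encoding)."""
        out: list[ConceptNode] = []

        def walk(node: ConceptNode) -> None:
            if node.is_leaf():
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, name: str, tree: Mapping[str, Any]) -> "ConceptHierarchy":
        def build(d: Mapping[str, Any]) -> ConceptNode:
            try:
                node = ConceptNode(id=str(d["id"]), label=str(d.get("label", d["id"])))
            except KeyError as exc:
                raise SchemaError(f"hierarchy {name!r}: concept without {exc} field")
            node.children = [build(c) for c in d.get("children", [])]
            return node

        return cls(name, build(tree))

    def to_dict(self) -> dict[str, Any]:
        def dump(node: ConceptNode) -> dict[str, Any]:
            d: dict[str, Any] = {"id": node.id, "label": node.label}
            if node.children:
                d["children"] = [dump(c) for c in node.children]
            return d

        return {"name": self.name, "root": dump(self.root)}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConceptHierarchy) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"ConceptHierarchy({self.name!r}, {len(self._index)} concepts)"


def lowest_common_ancestor(h: ConceptHierarchy, a: str, b: str) -> ConceptNode:
    """Deepest node that is an ancestor-or-self of both ``a`` and ``b``."""
    path_a = h.node(a).ancestors_or_self()
    path_b = h.node(b).ancestors_or_self()
    lca = path_a[0]
    for na, nb in zip(path_a, path_b):
        if na.id != nb.id:
            break
        lca = na
    return lca


# ---------------------------------------------------------------------------
# Attributes, entities, rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttributeSpec:
    """Typed attribute declaration, named ``Entity.Attribute``."""

    name: str
    kind: str
    unit: Optional[str] = None
    numeric_range: Optional[tuple[float, float]] = None
    categories: Optional[tuple[str, ...]] = None
    hierarchy: Optional[str] = None
    nullable: bool = True

    def __post_init__(self) -> None:
        if "." not in self.name:
            raise SchemaError(f"attribute name {self.name!r} is not of form Entity.Attribute")
        if self.kind not in ATTRIBUTE_KINDS:
            raise SchemaError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "hierarchical" and not self.hierarchy:
            raise SchemaError(f"hierarchical attribute {self.name!r} must name a hierarchy")
        if self.kind == "categorical" and not self.categories:
            raise SchemaError(f"categorical attribute {self.name!r} must list categories")
        if self.numeric_range is not None:
            lo, hi = self.numeric_range
            if not lo < hi:
                raise SchemaError(f"attribute {self.name!r}: numeric range must have min < max")

    @property
    def entity(self) -> str:
        return self.name.split(".", 1)[0]

    @property
    def short_name(self) -> str:
        return self.name.split(".", 1)[1]


@dataclass(frozen=True)
class EntitySpec:
    """Entity declaration; children point to their parent via a foreign key."""

    name: str
    parent: Optional[str] = None
    foreign_key: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.parent is None) != (self.foreign_key is None):
            raise SchemaError(
                f"entity {self.name!r}: parent and foreign_key must be given together"
            )


@dataclass(frozen=True)
class DerivedVariableDef:
    """A calculated variable defined by a safe declarative expression.

    Supported expression forms: arithmetic over attributes of the same
    entity (``Aneurysm.Width * 2``), counts of related child records
    (``count(Aneurysm)``) and whole-year date differences
    (``years_between(Patient.DiagnosisDate, Patient.BirthDate)``).
    """

    name: str
    expression: str

    @property
    def entity(self) -> str:
        return self.name.split(".", 1)[0]


@dataclass(frozen=True)
class Rule:
    """One validation rule applied per record.

    kinds: ``range`` (numeric bounds), ``membership`` (value in a fixed
    set), ``boolean`` (parsable truth value), ``not_null`` and ``implies``
    (cross-field: when ``attribute == when_value``, ``then_attribute``
    must equal ``then_value``).
    """

    kind: str
    attribute: str
    params: tuple[tuple[str, Any], ...] = ()

    def param(self, key: str) -> Any:
        return dict(self.params)[key]


@dataclass(frozen=True)
class Violation:
    record_id: Optional[str]
    attribute: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    """All rule violations found in a record set, with per-rule counts."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.violations

    def counts_by_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.violations:
            counts[v.rule] = counts.get(v.rule, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": v.record_id,
                    "attribute": v.attribute,
                    "rule": v.rule,
                    "message": v.message,
                }
                for v in self.violations
            ],
            columns=["record_id", "attribute", "rule", "message"],
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_violations": len(self.violations),
            "counts_by_rule": self.counts_by_rule(),
            "violations": [
                {
                    "record_id": v.record_id,
                    "attribute": v.attribute,
                    "rule": v.rule,
                    "message": v.message,
                }
                for v in self.violations
            ],
        }


# ---------------------------------------------------------------------------
# The ontology itself
# ---------------------------------------------------------------------------


class DomainOntology:
    """Fully linked domain model; constructor checks all cross-references."""

    def __init__(
        self,
        name: str,
        entities: Sequence[EntitySpec],
        attributes: Sequence[AttributeSpec],
        hierarchies: Sequence[ConceptHierarchy] = (),
        derived: Sequence[DerivedVariableDef] = (),
        rules: Sequence[Rule] = (),
    ):
        self.name = name
        self.entities: dict[str, EntitySpec] = {}
        for e in entities:
            if e.name in self.entities:
                raise SchemaError(f"duplicate entity {e.name!r}")
            self.entities[e.name] = e
        self.hierarchies: dict[str, ConceptHierarchy] = {h.name: h for h in hierarchies}
        self.attributes: dict[str, AttributeSpec] = {}
        for a in attributes:
            if a.name in self.attributes:
                raise SchemaError(f"duplicate attribute {a.name!r}")
            self.attributes[a.name] = a
        self.derived: list[DerivedVariableDef] = list(derived)
        self.rules: list[Rule] = list(rules)
        self._check_links()

    # -- linkage invariants -------------------------------------------------

    def _check_links(self) -> None:
        for e in self.entities.values():
            if e.parent is not None and e.parent not in self.entities:
                raise DanglingReferenceError(
                    f"entity {e.name!r} references undeclared parent {e.parent!r}"
                )
        # relation graph must be acyclic
        for e in self.entities.values():
            seen = {e.name}
            cur = e.parent
            while cur is not None:
                if cur in seen:
                    raise SchemaError(f"cycle in entity relations through {cur!r}")
                seen.add(cur)
                cur = self.entities[cur].parent
        for a in self.attributes.values():
            if a.entity not in self.entities:
                raise DanglingReferenceError(
                    f"attribute {a.name!r} belongs to undeclared entity {a.entity!r}"
                )
            if a.kind == "hierarchical" and a.hierarchy not in self.hierarchies:
                raise DanglingReferenceError(
                    f"attribute {a.name!r} references undeclared hierarchy {a.hierarchy!r}"
                )
        derived_names = {d.name for d in self.derived}
        for d in self.derived:
            if d.name not in self.attributes:
                raise DanglingReferenceError(
                    f"derived variable {d.name!r} has no matching attribute declaration"
                )
            for ref in _expression_references(d.expression):
                if ref in self.entities:
                    continue
                if ref not in self.attributes:
                    raise DanglingReferenceError(
                        f"derived variable {d.name!r} references unknown {ref!r}"
                    )
        self._check_derived_acyclic(derived_names)
        for r in self.rules:
            if r.attribute not in self.attributes:
                raise DanglingReferenceError(
                    f"rule on undeclared attribute {r.attribute!r}"
                )

    def _check_derived_acyclic(self, derived_names: set[str]) -> None:
        graph = {
            d.name: [r for r in _expression_references(d.expression) if r in derived_names]
            for d in self.derived
        }
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            if state.get(n) == 1:
                raise SchemaError(f"cycle among derived variables through {n!r}")
            if state.get(n) == 2:
                return
            state[n] = 1
            for m in graph.get(n, []):
                visit(m)
            state[n] = 2

        for n in graph:
            visit(n)

    # -- queries ------------------------------------------------------------

    def attribute(self, name: str) -> AttributeSpec:
        try:
            return self.attributes[name]
        except KeyError:
            raise DanglingReferenceError(
                f"unknown attribute {name!r}; declared: {sorted(self.attributes)}"
            ) from None

    def hierarchy(self, name: str) -> ConceptHierarchy:
        try:
            return self.hierarchies[name]
        except KeyError:
            raise DanglingReferenceError(f"unknown hierarchy {name!r}") from None

    def entity_attributes(self, entity: str) -> list[AttributeSpec]:
        return [a for a in self.attributes.values() if a.entity == entity]

    def child_entities(self, entity: str) -> list[EntitySpec]:
        return [e for e in self.entities.values() if e.parent == entity]

    def derived_names(self) -> set[str]:
        return {d.name for d in self.derived}

    def attribute_hierarchy(self, name: str) -> ConceptHierarchy:
        spec = self.attribute(name)
        if spec.kind != "hierarchical" or spec.hierarchy is None:
            raise DanglingReferenceError(f"attribute {name!r} is not hierarchical")
        return self.hierarchy(spec.hierarchy)

    # -- rules --------------------------------------------------------------

    def all_rules(self) -> list[Rule]:
        """Automatic per-attribute rules plus the explicitly declared ones."""
        rules: list[Rule] = []
        for a in self.attributes.values():
            if a.kind == "numeric" and a.numeric_range is not None:
                rules.append(
                    Rule("range", a.name, (("min", a.numeric_range[0]), ("max", a.numeric_range[1])))
                )
            elif a.kind == "categorical":
                rules.append(Rule("membership", a.name, (("values", tuple(a.categories or ())),)))
            elif a.kind == "hierarchical":
                h = self.hierarchy(a.hierarchy)  # type: ignore[arg-type]
                rules.append(Rule("membership", a.name, (("values", tuple(h.leaf_ids())),)))
            elif a.kind == "boolean":
                rules.append(Rule("boolean", a.name))
            if not a.nullable:
                rules.append(Rule("not_null", a.name))
        rules.extend(self.rules)
        return rules

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "entities": [
                {k: v for k, v in (("name", e.name), ("parent", e.parent), ("foreign_key", e.foreign_key)) if v is not None}
                for e in self.entities.values()
            ],
            "hierarchies": [h.to_dict() for h in self.hierarchies.values()],
            "attributes": [
                {
                    k: v
                    for k, v in (
                        ("name", a.name),
                        ("kind", a.kind),
                        ("unit", a.unit),
                        ("range", list(a.numeric_range) if a.numeric_range else None),
                        ("categories", list(a.categories) if a.categories else None),
                        ("hierarchy", a.hierarchy),
                        ("nullable", a.nullable),
                    )
                    if v is not None
                }
                for a in self.attributes.values()
            ],
            "derived": [{"name": d.name, "expression": d.expression} for d in self.derived],
            "rules": [
                {"kind": r.kind, "attribute": r.attribute, **dict(r.params)} for r in self.rules
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DomainOntology) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"DomainOntology({self.name!r}, entities={list(self.entities)}, "
            f"{len(self.attributes)} attributes)"
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_ontology(source: Union[str, Path]) -> DomainOntology:
    """Parse a versioned YAML ontology document into a linked ontology.

    ``source`` may be a filesystem path or a YAML string.  Raises
    :class:`SchemaError` on malformed documents and
    :class:`DanglingReferenceError` on unresolved references.
    """
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"ontology document does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise SchemaError("ontology document must be a mapping at top level")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unrecognized schema_version {version!r} (expected {SCHEMA_VERSION})")
    return _ontology_from_dict(doc)


def _ontology_from_dict(doc: Mapping[str, Any]) -> DomainOntology:
    try:
        entities = [EntitySpec(**e) for e in doc.get("entities", [])]
        hierarchies = [
            ConceptHierarchy.from_dict(h["name"], h["root"]) for h in doc.get("hierarchies", [])
        ]
        attributes = []
        for a in doc.get("attributes", []):
            a = dict(a)
            rng = a.pop("range", None)
            attributes.append(
                AttributeSpec(
                    name=a["name"],
                    kind=a["kind"],
                    unit=a.get("unit"),
                    numeric_range=tuple(rng) if rng else None,
                    categories=tuple(a["categories"]) if a.get("categories") else None,
                    hierarchy=a.get("hierarchy"),
                    nullable=bool(a.get("nullable", True)),
                )
            )
        derived = [DerivedVariableDef(d["name"], d["expression"]) for d in doc.get("derived", [])]
        rules = []
        for r in doc.get("rules", []):
            r = dict(r)
            kind = r.pop("kind")
            attribute = r.pop("attribute")
            rules.append(Rule(kind, attribute, tuple(sorted(r.items()))))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed ontology document field: {exc}") from exc
    return DomainOntology(
        name=str(doc.get("name", "ontology")),
        entities=entities,
        attributes=attributes,
        hierarchies=hierarchies,
        derived=derived,
        rules=rules,
    )


def load_bundled_ontology(name: str = "aneurysm_registry") -> DomainOntology:
    """Load an ontology document shipped inside the package."""
    text = resources.files("ontokdd.data").joinpath(f"{name}.ontology.yaml").read_text("utf-8")
    return load_ontology(text)


def bundled_ontology_text(name: str = "aneurysm_registry") -> str:
    return resources.files("ontokdd.data").joinpath(f"{name}.ontology.yaml").read_text("utf-8")


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------


def parse_boolean(values: pd.Series) -> pd.Series:
    """Coerce a boolean attribute column (bool dtype or common spellings)."""
    if values.dtype == bool:
        return values
    out = pd.Series(index=values.index, dtype=object)
    for idx, v in values.items():
        if isinstance(v, (bool, np.bool_)):
            out[idx] = bool(v)
        elif v is None or (isinstance(v, float) and np.isnan(v)):
            out[idx] = None
        else:
            s = str(v).strip().lower()
            out[idx] = True if s in _TRUE else False if s in _FALSE else None
    return out


def _record_ids(df: pd.DataFrame) -> pd.Series:
    if "id" in df.columns:
        return df["id"].astype(str)
    return pd.Series(df.index.astype(str), index=df.index)


def validate_records(
    ontology: DomainOntology, records: Mapping[str, pd.DataFrame]
) -> ValidationReport:
    """Check every record of every entity against the ontology's rules.

    ``records`` maps entity name to a DataFrame whose columns are dotted
    attribute names plus the structural columns ``id`` and the declared
    foreign key.  Unknown columns yield a structural violation entry rather
    than an exception; unknown entities likewise.
    """
    report = ValidationReport()
    rules_by_attr: dict[str, list[Rule]] = {}
    for r in ontology.all_rules():
        rules_by_attr.setdefault(r.attribute, []).append(r)

    for entity, df in records.items():
        if entity not in ontology.entities:
            report.violations.append(
                Violation(None, entity, "structural", f"unknown entity {entity!r}")
            )
            continue
        espec = ontology.entities[entity]
        structural = {"id"}
        if espec.foreign_key:
            structural.add(espec.foreign_key)
        declared = {a.name for a in ontology.entity_attributes(entity)}
        ids = _record_ids(df)
        for col in df.columns:
            if col in structural:
                continue
            if col not in declared:
                report.violations.append(
                    Violation(None, col, "structural", f"unknown column {col!r} on entity {entity!r}")
                )
                continue
            spec = ontology.attribute(col)
            for rule in rules_by_attr.get(col, []):
                _apply_rule(rule, spec, df[col], ids, df, report)
        # cross-field rules whose condition attribute lives on this entity
        # are handled above through rules_by_attr keyed on the attribute.
    return report


def _apply_rule(
    rule: Rule,
    spec: AttributeSpec,
    col: pd.Series,
    ids: pd.Series,
    df: pd.DataFrame,
    report: ValidationReport,
) -> None:
    if rule.kind == "range":
        lo, hi = rule.param("min"), rule.param("max")
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        for idx in col.index[bad]:
            report.violations.append(
                Violation(
                    ids[idx],
                    spec.name,
                    "range",
                    f"{spec.name}={col[idx]!r} outside [{lo}, {hi}]"
                    + (f" {spec.unit}" if spec.unit else ""),
                )
            )
        nonnum = col.notna() & vals.isna()
        for idx in col.index[nonnum]:
            report.violations.append(
                Violation(ids[idx], spec.name, "range", f"{spec.name}={col[idx]!r} is not numeric")
            )
    elif rule.kind == "membership":
        allowed = set(rule.param("values"))
        bad = col.notna() & ~col.astype(str).isin({str(v) for v in allowed})
        for idx in col.index[bad]:
            report.violations.append(
                Violation(
                    ids[idx],
                    spec.name,
                    "membership",
                    f"{spec.name}={col[idx]!r} not in {sorted(map(str, allowed))}",
                )
            )
    elif rule.kind == "boolean":
        parsed = parse_boolean(col)
        bad = col.notna() & parsed.isna()
        for idx in col.index[bad]:
            report.violations.append(
                Violation(ids[idx], spec.name, "boolean", f"{spec.name}={col[idx]!r} is not boolean")
            )
    elif rule.kind == "not_null":
        bad = col.isna()
        for idx in col.index[bad]:
            report.violations.append(
                Violation(ids[idx], spec.name, "not_null", f"{spec.name} is missing")
            )
    elif rule.kind == "implies":
        when_value = rule.param("when_value")
        then_attr = rule.param("then_attribute")
        then_value = rule.param("then_value")
        if then_attr not in df.columns:
            return
        cond = col.astype(str) == str(when_value)
        if spec.kind == "boolean":
            cond = parse_boolean(col) == when_value
        then_col = df[then_attr]
        then_ok = then_col.astype(str) == str(then_value)
        bad = cond & ~then_ok
        for idx in col.index[bad]:
            report.violations.append(
                Violation(
                    ids[idx],
                    spec.name,
                    "implies",
                    f"{spec.name}={when_value!r} requires {then_attr}={then_value!r}, "
                    f"found {then_col[idx]!r}",
                )
            )
    else:
        raise SchemaError(f"unknown rule kind {rule.kind!r}")


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = {ast.Add, ast.Sub, ast.Mult, ast.Div}
_ALLOWED_FUNCS = {"count", "years_between"}


def _expression_references(expression: str) -> list[str]:
    """Attribute / entity names referenced by a derived-variable expression."""
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise SchemaError(f"derived expression {expression!r} does not parse: {exc}") from exc
    refs: list[str] = []

    def walk(node: ast.AST) -> None:
        if isinstance(node, ast.Attribute) and isinstance(node.value, ast.Name):
            refs.append(f"{node.value.id}.{node.attr}")
            return
        if isinstance(node, ast.Name):
            refs.append(node.id)
            return
        if isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_FUNCS):
                raise SchemaError(f"derived expression {expression!r}: disallowed call")
            for arg in node.args:
                walk(arg)
            return
        for child in ast.iter_child_nodes(node):
            walk(child)

    walk(tree.body)
    return refs


def _eval_expression(
    expression: str,
    entity: str,
    df: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    ontology: DomainOntology,
) -> pd.Series:
    tree = ast.parse(expression, mode="eval")

    def column(name: str) -> pd.Series:
        if name not in df.columns:
            raise SchemaError(
                f"derived expression {expression!r}: operand {name!r} missing from {entity!r} records"
            )
        col = df[name]
        numeric = pd.to_numeric(col, errors="coerce")
        # keep non-numeric columns (e.g. dates) as-is for functions like years_between
        if col.notna().any() and numeric.isna().all():
            return col
        return numeric

    def ev(node: ast.AST) -> Any:
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return node.value
        if isinstance(node, ast.Attribute) and isinstance(node.value, ast.Name):
            return column(f"{node.value.id}.{node.attr}")
        if isinstance(node, ast.Name):
            return column(node.id)
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -ev(node.operand)
        if isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_BINOPS:
            left, right = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            with np.errstate(divide="ignore", invalid="ignore"):
                out = left / right
            out = pd.Series(out, index=df.index) if not isinstance(out, pd.Series) else out
            n_bad = int(np.isinf(out).sum())
            if n_bad:
                logger.warning(
                    "derived expression %r: %d division-by-zero results set to null",
                    expression,
                    n_bad,
                )
            return out.replace([np.inf, -np.inf], np.nan)
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
            if node.func.id == "count":
                (arg,) = node.args
                if not isinstance(arg, ast.Name):
                    raise SchemaError(f"count() takes an entity name in {expression!r}")
                return _count_related(entity, arg.id, df, records, ontology)
            if node.func.id == "years_between":
                a, b = (ev(x) for x in node.args)
                da = pd.to_datetime(a, errors="coerce")
                db = pd.to_datetime(b, errors="coerce")
                years = (
                    da.dt.year
                    - db.dt.year
                    - (
                        (da.dt.month < db.dt.month)
                        | ((da.dt.month == db.dt.month) & (da.dt.day < db.dt.day))
                    ).astype(int)
                )
                return years.astype("float64")
        raise SchemaError(f"derived expression {expression!r}: unsupported construct")

    result = ev(tree)
    if not isinstance(result, pd.Series):
        result = pd.Series(result, index=df.index)
    return result


def _count_related(
    entity: str,
    child_entity: str,
    df: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    ontology: DomainOntology,
) -> pd.Series:
    child_spec = ontology.entities.get(child_entity)
    if child_spec is None or child_spec.parent != entity:
        raise SchemaError(f"count({child_entity}) is not a child of entity {entity!r}")
    fk = child_spec.foreign_key
    child_df = records.get(child_entity)
    ids = _record_ids(df)
    if child_df is None or fk not in child_df.columns:
        return pd.Series(0.0, index=df.index)
    counts = child_df[fk].astype(str).value_counts()
    return ids.map(counts).fillna(0).astype(float)


def evaluate_derived(
    ontology: DomainOntology, records: Mapping[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Append every derived column to its entity's records.

    Idempotent and independent of record order: derived columns are
    deterministic functions of the input records, evaluated in dependency
    order.  Existing columns with the same name are recomputed.
    """
    out = {entity: df.copy() for entity, df in records.items()}
    derived_names = ontology.derived_names()
    order = _topological_order(ontology, derived_names)
    for d in order:
        if d.entity not in out:
            continue
        out[d.entity][d.name] = _eval_expression(
            d.expression, d.entity, out[d.entity], out, ontology
        ).values
    return out


def _topological_order(
    ontology: DomainOntology, derived_names: set[str]
) -> list[DerivedVariableDef]:
    by_name = {d.name: d for d in ontology.derived}
    done: list[DerivedVariableDef] = []
    state: dict[str, int] = {}

    def visit(name: str) -> None:
        if state.get(name) == 2:
            return
        state[name] = 1
        for ref in _expression_references(by_name[name].expression):
            if ref in derived_names and ref != name:
                visit(ref)
        state[name] = 2
        done.append(by_name[name])

    for name in by_name:
        visit(name)
    return done


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def read_records(data_dir: Union[str, Path], ontology: DomainOntology) -> dict[str, pd.DataFrame]:
    """Read one ``<Entity>.csv`` per declared entity from ``data_dir``."""
    data_dir = Path(data_dir)
    records: dict[str, pd.DataFrame] = {}
    for entity in ontology.entities:
        path = data_dir / f"{entity}.csv"
        if path.exists():
            records[entity] = pd.read_csv(path, dtype={"id": str, "patient_id": str})
    if not records:
        raise FileNotFoundError(f"no entity CSV files found in {data_dir}")
    return records


def write_records(
    records: Mapping[str, pd.DataFrame], data_dir: Union[str, Path]
) -> list[Path]:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for entity, df in records.items():
        path = data_dir / f"{entity}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
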