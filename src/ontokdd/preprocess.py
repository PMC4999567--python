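"""Ontology-guided transformation of raw records into model-ready tables.

The entry point is :func:`flatten`, which joins a parent entity's
attributes onto each child record (e.g. patient attributes repeated on
every aneurysm of that patient) after evaluating derived variables, and
:func:`encode`, which turns a selected feature set plus binary target into
a dense numeric :class:`FeatureMatrix` for the model-screening step.  All
structural decisions (which columns are numeric, which categories exist,
which hierarchy a code belongs to) come from the attached ontology
metadata, never from the data itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError, DanglingReferenceError
from .ontology import (
    AttributeSpec,
    ConceptHierarchy,
    DomainOntology,
    evaluate_derived,
    parse_boolean,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisTable:
    """Flat per-record feature table at a chosen entity grain.

    ``data`` is indexed by record id; every column carries its
    :class:`AttributeSpec` in ``columns``.  ``hierarchies`` holds the
    concept hierarchies referenced by hierarchical columns so that
    downstream modules need no separate ontology handle.
    """

    grain: str
    data: pd.DataFrame
    columns: dict[str, AttributeSpec]
    hierarchies: dict[str, ConceptHierarchy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ContractError("duplicate column names in analysis table")
        missing = [c for c in cols if c not in self.columns]
        if missing:
            raise ContractError(f"columns without ontology metadata: {missing}")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def spec(self, name: str) -> AttributeSpec:
        try:
            return self.columns[name]
        except KeyError:
            raise DanglingReferenceError(
                f"unknown column {name!r}; available: {list(self.columns)}"
            ) from None

    def hierarchy_for(self, name: str) -> ConceptHierarchy:
        spec = self.spec(name)
        if spec.kind != "hierarchical" or spec.hierarchy is None:
            raise DanglingReferenceError(f"column {name!r} is not hierarchical")
        return self.hierarchies[spec.hierarchy]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the table plus a sidecar ``.meta.json`` naming each column."""
        path = Path(path)
        self.data.to_csv(path, index_label="id")
        meta = {
            "grain": self.grain,
            "columns": {
                name: {
                    "kind": s.kind,
                    "unit": s.unit,
                    "hierarchy": s.hierarchy,
                    "categories": list(s.categories) if s.categories else None,
                }
                for name, s in self.columns.items()
            },
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path], ontology: DomainOntology) -> "AnalysisTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="id")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text("utf-8"))
        columns = {name: ontology.attribute(name) for name in df.columns}
        hierarchies = {
            s.hierarchy: ontology.hierarchy(s.hierarchy)
            for s in columns.values()
            if s.kind == "hierarchical" and s.hierarchy
        }
        return cls(grain=meta["grain"], data=df, columns=columns, hierarchies=hierarchies)


@dataclass
class FeatureMatrix:
    """Dense numeric design matrix with a binary label vector.

    ``column_map`` records, for each matrix column, the source attribute
    and (for one-hot columns) the category level it indicates.
    """

    values: np.ndarray
    column_map: list[tuple[str, Optional[str]]]
    label: np.ndarray
    row_ids: list[str]
    positive_class: str = "True"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if self.values.ndim != 2:
            raise ContractError("feature matrix must be 2-D")
        n, p = self.values.shape
        if len(self.column_map) != p:
            raise ContractError("column_map must cover every matrix column")
        if len(self.label) != n or len(self.row_ids) != n:
            raise ContractError("label / row_ids length mismatch")
        if np.isnan(self.values).any():
            raise ContractError("feature matrix contains missing values")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise ContractError("label vector must be binary 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return sorted({attr for attr, _ in self.column_map})


# ---------------------------------------------------------------------------
# flatten
# ---------------------------------------------------------------------------


def flatten(
    ontology: DomainOntology,
    records: Mapping[str, pd.DataFrame],
    grain: str = "Aneurysm",
) -> AnalysisTable:
    """Build one row per ``grain`` record, joining parent attributes on.

    Derived variables are evaluated first; orphan child records (foreign
    key not resolving to a parent) are excluded with a logged count.
    """
    if grain not in ontology.entities:
        raise DanglingReferenceError(f"unknown grain entity {grain!r}")
    records = evaluate_derived(ontology, records)
    grain_spec = ontology.entities[grain]
    df = records[grain].copy()
    if "id" in df.columns:
        df = df.set_index(df["id"].astype(str)).drop(columns=["id"])
    else:
        df.index = df.index.astype(str)

    columns: dict[str, AttributeSpec] = {}
    for a in ontology.entity_attributes(grain):
        if a.name in df.columns:
            columns[a.name] = a

    parent = grain_spec.parent
    fk = grain_spec.foreign_key
    if parent is not None and fk is not None and parent in records:
        pdf = records[parent].copy()
        if "id" in pdf.columns:
            pdf = pdf.set_index(pdf["id"].astype(str)).drop(columns=["id"])
        else:
            pdf.index = pdf.index.astype(str)
        fk_vals = df[fk].astype(str)
        orphan = ~fk_vals.isin(pdf.index)
        if orphan.any():
            logger.warning(
                "flatten: excluded %d orphan %s record(s) with unresolved %s",
                int(orphan.sum()),
                grain,
                fk,
            )
            df = df[~orphan]
            fk_vals = fk_vals[~orphan]
        for a in ontology.entity_attributes(parent):
            if a.name in pdf.columns:
                df[a.name] = pdf[a.name].reindex(fk_vals.values).values
                columns[a.name] = a
        df = df.drop(columns=[fk])

    keep = [c for c in df.columns if c in columns]
    df = df[keep]
    # coerce typed columns so downstream code sees uniform dtypes
    for name, spec in columns.items():
        if spec.kind == "numeric":
            df[name] = pd.to_numeric(df[name], errors="coerce")
        elif spec.kind == "boolean":
            df[name] = parse_boolean(df[name])
    hierarchies = {
        s.hierarchy: ontology.hierarchy(s.hierarchy)
        for s in columns.values()
        if s.kind == "hierarchical" and s.hierarchy
    }
    return AnalysisTable(grain=grain, data=df, columns=columns, hierarchies=hierarchies)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_numeric(column: Sequence[float], method: str = "minmax") -> np.ndarray:
    """Scale a numeric column to [0, 1].

    Min-max scaling maps the observed minimum to 0 and maximum to 1.  A
    constant column maps to 0.5 everywhere (it carries no distance
    information either way).  Missing values propagate unchanged.
    """
    if method != "minmax":
        raise ContractError(f"unknown normalization method {method!r}")
    x = np.asarray(column, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ContractError("cannot normalize an all-missing column")
    lo, hi = x[finite].min(), x[finite].max()
    if hi == lo:
        out = np.full_like(x, 0.5)
        out[~finite] = np.nan
        return out
    out = (x - lo) / (hi - lo)
    out[~finite] = np.nan
    return out


def normalize_table(table: AnalysisTable, features: Sequence[str]) -> AnalysisTable:
    """Return a copy of ``table`` with the numeric ``features`` min-max scaled."""
    df = table.data.copy()
    for name in features:
        spec = table.spec(name)
        if spec.kind == "numeric":
            try:
                df[name] = normalize_numeric(df[name].to_numpy(dtype=float))
            except ContractError as exc:
                raise ContractError(f"{name}: {exc}") from exc
    return AnalysisTable(
        grain=table.grain, data=df, columns=dict(table.columns), hierarchies=dict(table.hierarchies)
    )


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _levels_for(spec: AttributeSpec, table: AnalysisTable) -> list[str]:
    if spec.kind == "categorical":
        return list(spec.categories or ())
    if spec.kind == "hierarchical":
        return table.hierarchy_for(spec.name).leaf_ids()
    raise ContractError(f"no categorical levels for {spec.name!r}")


def encode(
    table: AnalysisTable,
    features: Sequence[str],
    target: str,
) -> FeatureMatrix:
    """Encode selected features and a binary target into a FeatureMatrix.

    Numeric attributes pass through unscaled (per-algorithm standardization
    happens inside cross-validation folds later); categorical and
    hierarchical attributes are one-hot expanded to their declared leaf
    categories; boolean attributes become a single 0/1 indicator.  Rows
    with a missing value in any used column are dropped with a logged
    count (listwise deletion).  The positive class is ``True`` for boolean
    targets; for a two-valued non-boolean target the lexicographically
    larger observed value is coded 1 and recorded in ``positive_class``.
    """
    if not features:
        raise ContractError("feature list must be non-empty")
    if target in features:
        raise ContractError(
            f"target {target!r} may not appear among the features (leakage guard)"
        )
    for name in list(features) + [target]:
        table.spec(name)

    used = list(features) + [target]
    sub = table.data[used].copy()
    tspec = table.spec(target)
    if tspec.kind == "boolean":
        sub[target] = parse_boolean(sub[target])
    n_before = len(sub)
    sub = sub.dropna(axis=0, how="any")
    dropped = n_before - len(sub)
    if dropped:
        logger.info("encode: dropped %d row(s) with missing feature/target values", dropped)

    # ----- target coding
    tvals = sub[target]
    if tspec.kind == "boolean":
        label = tvals.astype(bool).astype(int).to_numpy()
        positive = "True"
    else:
        observed = sorted(map(str, tvals.unique()))
        if len(observed) != 2:
            raise ContractError(
                f"target {target!r} must have exactly 2 observed classes, found {observed}"
            )
        positive = observed[1]
        label = (tvals.astype(str) == positive).astype(int).to_numpy()
    if len(set(label)) != 2:
        raise ContractError(f"target {target!r} must have exactly 2 observed classes")

    # ----- feature blocks
    blocks: list[np.ndarray] = []
    column_map: list[tuple[str, Optional[str]]] = []
    for name in features:
        spec = table.spec(name)
        col = sub[name]
        if spec.kind == "numeric":
            blocks.append(col.to_numpy(dtype=float)[:, None])
            column_map.append((name, None))
        elif spec.kind == "boolean":
            blocks.append(parse_boolean(col).astype(bool).astype(float).to_numpy()[:, None])
            column_map.append((name, None))
        else:
            levels = _levels_for(spec, table)
            vals = col.astype(str)
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ContractError(f"{name}: values outside declared categories: {sorted(unknown)}")
            onehot = np.column_stack([(vals == lv).to_numpy(dtype=float) for lv in levels])
            blocks.append(onehot)
            column_map.extend((name, lv) for lv in levels)

    values = np.hstack(blocks)
    return FeatureMatrix(
        values=values,
        column_map=column_map,
        label=label,
        row_ids=[str(i) for i in sub.index],
        positive_class=positive,
    )
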