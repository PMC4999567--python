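"""Mixed-type pairwise dissimilarity with hierarchy-aware categoricals.

Numeric attributes (min-max normalized to [0, 1]) contribute a normalized
Euclidean distance; categorical attributes contribute an extended Jaccard
dissimilarity in which the exact-match indicator is replaced, for
hierarchical attributes, by the Wu-Palmer similarity
``2 * depth(LCA) / (depth(a) + depth(b))`` on the concept hierarchy.  The
two blocks are combined as an attribute-count-weighted average
(Gower-style), so every selected attribute carries equal weight.

Only pseudo-metric properties are claimed (symmetry, zero diagonal,
bounds); the graded hierarchical similarity does not guarantee the
triangle inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError
from .ontology import AttributeSpec, ConceptHierarchy, lowest_common_ancestor
from .preprocess import AnalysisTable

logger = logging.getLogger(__name__)

_NORMALIZED_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with provenance."""

    values: np.ndarray
    row_ids: list[str]
    feature_set: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ContractError("distance matrix must be square")
        if d.shape[0] != len(self.row_ids):
            raise ContractError("row_ids length must match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ContractError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ContractError("distance matrix diagonal must be zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-9:
            raise ContractError("distances must lie in [0, 1]")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.values, index=self.row_ids, columns=self.row_ids).to_csv(path)


# ---------------------------------------------------------------------------
# component similarities
# ---------------------------------------------------------------------------


def concept_similarity(h: ConceptHierarchy, a: str, b: str) -> float:
    """Wu-Palmer similarity of two concepts in a rooted hierarchy.

    Defined as 1 when ``a == b`` (covering the root compared with itself);
    otherwise ``2*depth(LCA)/(depth(a)+depth(b))``, which is 0 exactly when
    the concepts share no ancestor below the root.
    """
    if a == b:
        h.node(a)  # still validate the id
        return 1.0
    da, db = h.depth(a), h.depth(b)
    lca = lowest_common_ancestor(h, a, b)
    return 2.0 * lca.depth / (da + db)


def _sim_lookup(
    spec: AttributeSpec, levels: Sequence[str], hierarchy: Optional[ConceptHierarchy]
) -> np.ndarray:
    """Level-by-level similarity table for one categorical attribute."""
    k = len(levels)
    if spec.kind == "hierarchical":
        assert hierarchy is not None
        sim = np.empty((k, k))
        for i, a in enumerate(levels):
            for j, b in enumerate(levels):
                sim[i, j] = concept_similarity(hierarchy, a, b)
        return sim
    return np.eye(k)


def categorical_dissimilarity(
    x: Mapping[str, object],
    y: Mapping[str, object],
    specs: Sequence[AttributeSpec],
    hierarchies: Optional[Mapping[str, ConceptHierarchy]] = None,
) -> float:
    """Extended Jaccard dissimilarity of two records over categorical attributes.

    ``1 - mean(similarity)`` over the attributes comparable in both
    records, where similarity is the exact-match indicator for flat
    categoricals / booleans and the hierarchy similarity for hierarchical
    attributes.  Returns ``nan`` when no attribute is comparable; the
    matrix-level combiner resolves that case.
    """
    if not specs:
        raise ContractError("need at least one categorical attribute")
    hierarchies = hierarchies or {}
    total, m = 0.0, 0
    for spec in specs:
        xv, yv = x.get(spec.name), y.get(spec.name)
        if _is_missing(xv) or _is_missing(yv):
            continue
        if spec.kind == "hierarchical":
            h = hierarchies[spec.hierarchy]  # type: ignore[index]
            total += concept_similarity(h, str(xv), str(yv))
        else:
            total += 1.0 if xv == yv else 0.0
        m += 1
    if m == 0:
        return float("nan")
    return 1.0 - total / m


def numeric_dissimilarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Normalized Euclidean distance over [0,1]-scaled numeric attributes.

    ``sqrt(sum((x_j - y_j)^2) / p)`` where ``p`` counts the attributes
    comparable in both records; dividing by the attribute count bounds the
    result in [0, 1].  Returns ``nan`` when nothing is comparable.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    for arr in (xa, ya):
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < -_NORMALIZED_TOL or finite.max() > 1 + _NORMALIZED_TOL):
            raise ContractError("numeric inputs must be min-max normalized to [0, 1]")
    both = np.isfinite(xa) & np.isfinite(ya)
    p = int(both.sum())
    if p == 0:
        return float("nan")
    return float(np.sqrt(np.sum((xa[both] - ya[both]) ** 2) / p))


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------


def mixed_distance_matrix(table: AnalysisTable, features: Sequence[str]) -> DistanceMatrix:
    """Pairwise mixed-type distance over the selected attributes.

    ``d_ij = (p_num * d_num + p_cat * d_cat) / (p_num + p_cat)`` with the
    attribute counts taken per pair over the attributes comparable in both
    records (missing values are excluded pairwise).  Numeric columns must
    already be normalized to [0, 1] (see
    :func:`ontokdd.preprocess.normalize_table`).  A pair with no comparable
    attribute at all receives distance 1 with a logged warning.
    """
    if not features:
        raise ContractError("feature list must be non-empty")
    n = table.n_rows
    if n < 2:
        raise ContractError("need at least 2 records for a distance matrix")

    num_specs = [table.spec(f) for f in features if table.spec(f).kind == "numeric"]
    cat_specs = [table.spec(f) for f in features if table.spec(f).kind != "numeric"]

    ss = np.zeros((n, n))        # sum of squared numeric differences
    num_cnt = np.zeros((n, n))   # comparable numeric attributes per pair
    sim_sum = np.zeros((n, n))   # summed categorical similarities
    cat_cnt = np.zeros((n, n))   # comparable categorical attributes per pair

    for spec in num_specs:
        col = table.data[spec.name].to_numpy(dtype=float)
        finite = np.isfinite(col)
        vals = col[finite]
        if vals.size and (vals.min() < -_NORMALIZED_TOL or vals.max() > 1 + _NORMALIZED_TOL):
            raise ContractError(
                f"{spec.name}: numeric feature must be min-max normalized to [0, 1]"
            )
        x = np.where(finite, col, 0.0)
        diff2 = (x[:, None] - x[None, :]) ** 2
        both = finite[:, None] & finite[None, :]
        ss += np.where(both, diff2, 0.0)
        num_cnt += both

    for spec in cat_specs:
        if spec.kind == "boolean":
            levels = ["False", "True"]
            raw = table.data[spec.name]
            vals = raw.map(lambda v: None if _is_missing(v) else str(bool(v)))
        else:
            if spec.kind == "categorical":
                levels = list(spec.categories or ())
            else:
                levels = table.hierarchy_for(spec.name).leaf_ids()
            raw = table.data[spec.name]
            vals = raw.map(lambda v: None if _is_missing(v) else str(v))
        level_index = {lv: i for i, lv in enumerate(levels)}
        codes = np.array([level_index.get(v, -1) if v is not None else -1 for v in vals])
        unknown = (codes == -1) & np.array([v is not None for v in vals])
        if unknown.any():
            raise ContractError(
                f"{spec.name}: values outside declared categories in rows "
                f"{list(np.where(unknown)[0][:5])}"
            )
        present = codes >= 0
        hierarchy = (
            table.hierarchy_for(spec.name) if spec.kind == "hierarchical" else None
        )
        sim = _sim_lookup(spec, levels, hierarchy)
        safe = np.where(present, codes, 0)
        pair_sim = sim[safe[:, None], safe[None, :]]
        both = present[:, None] & present[None, :]
        sim_sum += np.where(both, pair_sim, 0.0)
        cat_cnt += both

    with np.errstate(divide="ignore", invalid="ignore"):
        d_num = np.sqrt(np.where(num_cnt > 0, ss / np.maximum(num_cnt, 1), 0.0))
        d_cat = np.where(cat_cnt > 0, 1.0 - sim_sum / np.maximum(cat_cnt, 1), 0.0)
        total_cnt = num_cnt + cat_cnt
        d = np.where(
            total_cnt > 0,
            (num_cnt * d_num + cat_cnt * d_cat) / np.maximum(total_cnt, 1),
            1.0,
        )

    if (total_cnt == 0).any():
        off_diag = total_cnt.copy()
        np.fill_diagonal(off_diag, 1)
        n_bad = int((off_diag == 0).sum() // 2)
        if n_bad:
            logger.warning(
                "mixed_distance_matrix: %d pair(s) share no comparable attribute; distance set to 1",
                n_bad,
            )

    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, row_ids=table.row_ids, feature_set=tuple(features))
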