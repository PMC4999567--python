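"""Sammon's nonlinear mapping: distance matrix -> 2-D coordinates.

The mapping minimizes the Sammon stress

    E = [1 / sum_{i<j} d*_ij] * sum_{i<j} (d*_ij - d_ij)^2 / d*_ij

where ``d*`` are the input dissimilarities and ``d`` the Euclidean
distances between embedded points.  Small input distances are weighted up
by the ``1/d*`` factor, which is what makes the map preserve local
neighborhood topology better than classical metric scaling.  Optimization
follows the classical pseudo-Newton diagonal update with a step-size
"magic factor", with an explicit step-halving guard that keeps the stress
trace non-increasing.

Initialization defaults to the classical metric-scaling (principal
coordinate) solution, which makes the whole map deterministic; a seeded
uniform-random initialization is available as a fallback.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError
from .distances import DistanceMatrix, mixed_distance_matrix
from .preprocess import AnalysisTable, normalize_table

logger = logging.getLogger(__name__)

_EPS_FRACTION = 1e-6  # zero input distances replaced by this fraction of the max


@dataclass
class SammonConfig:
    max_iter: int = 500
    magic_factor: float = 0.3
    tol: float = 1e-9
    init: str = "pca"  # "pca" (principal coordinates) or "random"
    seed: int = 0


@dataclass
class Embedding:
    """2-D coordinates plus the stress trace of the optimization."""

    coords: np.ndarray
    stress: float
    trace: list[float]
    converged: bool
    seed: int
    row_ids: list[str]
    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ContractError("embedding coordinates must be finite")
        if self.stress < 0:
            raise ContractError("stress must be non-negative")

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"row_id": self.row_ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        ).to_csv(path, index=False)

    def metadata(self) -> dict[str, Any]:
        return {
            "stress": self.stress,
            "iterations": len(self.trace) - 1,
            "converged": self.converged,
            "seed": self.seed,
            "source": self.source,
        }

    def save_metadata(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------


def _prepare_dstar(D: np.ndarray) -> np.ndarray:
    """Replace zero off-diagonal input distances by a tiny epsilon."""
    Dstar = np.asarray(D, dtype=float).copy()
    n = Dstar.shape[0]
    off = ~np.eye(n, dtype=bool)
    dmax = Dstar.max()
    if dmax <= 0:
        raise ContractError("all-zero distance matrix: no topology to preserve")
    eps = _EPS_FRACTION * dmax
    zero_off = off & (Dstar < eps)
    Dstar[zero_off] = eps
    return Dstar


def sammon_stress(D: Union[DistanceMatrix, np.ndarray], coords: np.ndarray) -> float:
    """Sammon stress of ``coords`` against input distances ``D`` (>= 0)."""
    Dval = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if Dval.shape[0] < 2:
        raise ContractError("need at least 2 points")
    Dstar = _prepare_dstar(Dval)
    Y = np.asarray(coords, dtype=float)
    diff = Y[:, None, :] - Y[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(Dstar.shape[0], k=1)
    dstar_u, d_u = Dstar[iu], d[iu]
    c = dstar_u.sum()
    return float(((dstar_u - d_u) ** 2 / dstar_u).sum() / c)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def _init_coords(Dstar: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    n = Dstar.shape[0]
    if mode == "random":
        return rng.uniform(0.0, 1.0, size=(n, 2))
    if mode != "pca":
        raise ContractError(f"unknown init mode {mode!r}")
    # classical metric scaling (principal coordinates) on the input distances
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dstar**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    # degenerate spectra (e.g. identical rows) leave a flat axis: break ties
    for axis in range(2):
        if np.allclose(coords[:, axis], coords[0, axis]):
            coords[:, axis] += rng.normal(0.0, 1e-4 * max(Dstar.max(), 1.0), size=n)
    return coords


def _gradients(
    Y: np.ndarray, Dstar: np.ndarray, c: float, eps_d: float
) -> tuple[np.ndarray, np.ndarray]:
    diff = Y[:, None, :] - Y[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 1.0)
    d = np.maximum(d, eps_d)
    delta = Dstar - d
    with np.errstate(divide="ignore"):
        w = 1.0 / (Dstar * d)
    np.fill_diagonal(w, 0.0)
    g = (-2.0 / c) * np.einsum("ij,ijq->iq", w * delta, diff)
    ratio = 1.0 + delta / d
    h = (-2.0 / c) * (
        np.einsum("ij,ijq->iq", w * delta, np.ones_like(diff))
        - np.einsum("ij,ijq->iq", w / d * ratio, diff**2)
    )
    return g, h


def sammon_map(
    D: Union[DistanceMatrix, np.ndarray],
    max_iter: int = 500,
    magic_factor: float = 0.3,
    tol: float = 1e-9,
    init: str = "pca",
    seed: int = 0,
    row_ids: Optional[Sequence[str]] = None,
    source: Optional[dict[str, Any]] = None,
) -> Embedding:
    """Map a distance matrix to 2-D by pseudo-Newton descent on the stress.

    Stops when the relative stress change drops below ``tol`` or after
    ``max_iter`` iterations.  The step for each coordinate is
    ``magic_factor * gradient / |curvature|``; whenever a full step would
    increase the stress it is halved (up to 20 times), so the recorded
    trace is non-increasing and the final stress never exceeds the
    initialization's.  Deterministic given ``seed`` and ``init``.
    """
    if isinstance(D, DistanceMatrix):
        Dval, ids = D.values, D.row_ids
    else:
        Dval = np.asarray(D, dtype=float)
        ids = [str(i) for i in range(Dval.shape[0])]
    if row_ids is not None:
        ids = [str(r) for r in row_ids]
    n = Dval.shape[0]
    if n < 3:
        raise ContractError("need at least 3 records for a meaningful 2-D map")

    Dstar = _prepare_dstar(Dval)
    rng = np.random.default_rng(seed)
    Y = _init_coords(Dstar, init, rng)

    iu = np.triu_indices(n, k=1)
    c = float(Dstar[iu].sum())
    eps_d = _EPS_FRACTION * Dstar.max()

    def stress_of(Ycur: np.ndarray) -> float:
        diff = Ycur[:, None, :] - Ycur[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        return float(((Dstar[iu] - d[iu]) ** 2 / Dstar[iu]).sum() / c)

    trace = [stress_of(Y)]
    converged = False
    jittered = False
    for _ in range(max_iter):
        g, h = _gradients(Y, Dstar, c, eps_d)
        denom = np.abs(h)
        denom = np.maximum(denom, 1e-12)
        step = magic_factor * g / denom
        if not np.isfinite(step).all():
            if jittered:
                raise ContractError("non-finite update in Sammon iteration")
            logger.warning("sammon_map: non-finite update; jittering coordinates once")
            Y = Y + rng.normal(0.0, eps_d, size=Y.shape)
            jittered = True
            trace.append(min(trace[-1], stress_of(Y)))
            continue
        new_stress = None
        for _halving in range(20):
            cand = Y - step
            s = stress_of(cand)
            if s <= trace[-1] + 1e-12:
                new_stress = s
                Y = cand
                break
            step = step / 2.0
        if new_stress is None:
            converged = True  # no descent direction at this resolution
            break
        trace.append(new_stress)
        prev = trace[-2]
        if prev > 0 and abs(prev - new_stress) / max(new_stress, 1e-300) < tol:
            converged = True
            break
        if new_stress == 0.0:
            converged = True
            break

    return Embedding(
        coords=Y,
        stress=trace[-1],
        trace=trace,
        converged=converged,
        seed=seed,
        row_ids=ids,
        source=source or {},
    )


def embed_records(
    table: AnalysisTable,
    features: Sequence[str],
    config: Optional[SammonConfig] = None,
) -> Embedding:
    """Normalize -> mixed distance matrix -> Sammon map, with provenance."""
    config = config or SammonConfig()
    normalized = normalize_table(table, features)
    D = mixed_distance_matrix(normalized, features)
    return sammon_map(
        D,
        max_iter=config.max_iter,
        magic_factor=config.magic_factor,
        tol=config.tol,
        init=config.init,
        seed=config.seed,
        source={"features": list(features), "n": D.n, "grain": table.grain},
    )
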