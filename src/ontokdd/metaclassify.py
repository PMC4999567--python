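"""Meta-classification influence indicator.

Given a feature matrix and binary target, this module launches five
classifier families (naive Bayes, random forest, logistic regression,
RBF-kernel SVM with a coarse grid search, and a multi-layer perceptron)
over configuration grids, evaluates each configuration by stratified
tenfold cross-validated AUC (pooled out-of-fold scores), and consolidates
the best AUC per family into a :class:`ClassificationIndication`.  The
result is a screening signal -- "is there a measurable (possibly
nonlinear) influence of these features on this target?" -- not a
deployable model: no significance, causality or feature-subset claims are
made.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, ContractError
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("naive_bayes", "random_forest", "logistic_regression", "svm", "mlp")

#: printed abbreviations, in the customary reporting order
FAMILY_ABBREV = {
    "naive_bayes": "NB",
    "random_forest": "RF",
    "mlp": "MLP",
    "logistic_regression": "LR",
    "svm": "SVM",
}
REPORT_ORDER = ("naive_bayes", "random_forest", "mlp", "logistic_regression", "svm")

DEFAULT_THRESHOLDS = (0.60, 0.75)
VERDICTS = ("no_measurable_influence", "weak_indication", "strong_indication")


@dataclass(frozen=True)
class Configuration:
    """One named hyperparameter setting of a classifier family."""

    name: str
    params: tuple[tuple[str, Any], ...]

    @classmethod
    def make(cls, name: str, **params: Any) -> "Configuration":
        # sequences normalize to tuples so JSON round-trips compare equal
        norm = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in params.items()
        }
        return cls(name=name, params=tuple(sorted(norm.items())))

    def as_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "params": self.as_dict()}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Configuration":
        doc = json.loads(text)
        return cls.make(doc["name"], **doc["params"])


@dataclass
class AlgorithmGrid:
    """A classifier family plus the configurations to try for it."""

    family: str
    configurations: list[Configuration]
    scaling: bool

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.configurations:
            raise ConfigError(f"family {self.family!r}: configuration list must be non-empty")


@dataclass
class FoldPlan:
    """Stratified fold assignment for cross-validation."""

    k: int
    assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        folds = np.unique(self.assignments)
        if len(folds) != self.k or folds.min() != 0 or folds.max() != self.k - 1:
            raise ContractError("fold assignments must partition rows into k folds")

    def splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for f in range(self.k):
            test = np.where(self.assignments == f)[0]
            train = np.where(self.assignments != f)[0]
            out.append((train, test))
        return out


@dataclass
class FamilyResult:
    family: str
    best_auc: Optional[float]
    best_configuration: Optional[str]
    per_configuration: dict[str, Optional[float]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


@dataclass
class ClassificationIndication:
    """Consolidated best-AUC-per-family report with provenance."""

    families: dict[str, FamilyResult]
    overall_best: float
    overall_family: str
    verdict: str
    thresholds: tuple[float, float]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "families": {
                name: {
                    "best_auc": r.best_auc,
                    "best_configuration": r.best_configuration,
                    "per_configuration": r.per_configuration,
                    "failures": r.failures,
                }
                for name, r in self.families.items()
            },
            "overall_best": self.overall_best,
            "overall_family": self.overall_family,
            "verdict": self.verdict,
            "thresholds": list(self.thresholds),
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Human-readable table: families as columns, best AUC as cells."""
        header = [FAMILY_ABBREV[f] for f in REPORT_ORDER if f in self.families]
        cells = []
        for f in REPORT_ORDER:
            if f not in self.families:
                continue
            auc = self.families[f].best_auc
            cells.append("  n/a" if auc is None else f"{auc:.3f}")
        width = 8
        lines = [
            "Best cross-validated AUC per algorithm family",
            "".join(h.rjust(width) for h in header),
            "".join(c.rjust(width) for c in cells),
            f"overall best: {self.overall_best:.3f} ({FAMILY_ABBREV[self.overall_family]})",
            f"verdict: {self.verdict} (thresholds {self.thresholds[0]:.2f}/{self.thresholds[1]:.2f})",
            f"positive class: {self.provenance.get('positive_class', 'True')}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def make_fold_plan(labels: Sequence[int], k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment, deterministic for a fixed seed.

    When the smaller class has fewer than ``k`` members, ``k`` is reduced
    to that class size with a warning (stratification would otherwise
    leave folds without positives).
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("fold plan requires both classes present")
    min_class = int(counts.min())
    k_eff = min(k, min_class)
    if k_eff < 2:
        raise ContractError(f"smallest class has {min_class} member(s); cannot cross-validate")
    if k_eff < k:
        logger.warning("make_fold_plan: reduced k from %d to %d (smallest class size)", k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignments[test] = fold
    return FoldPlan(k=k_eff, assignments=assignments, seed=seed)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve in the Mann-Whitney form.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, counting ties as one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def default_grids() -> list[AlgorithmGrid]:
    """The five stock families with conventional, swappable grids.

    The SVM grid is a coarse exponential 3x3 grid over the regularization
    constant C and the RBF kernel width gamma; every other family carries
    at least two configurations.
    """
    c = Configuration.make
    svm_cfgs = [
        c(f"rbf_C{C}_g{g}", C=C, gamma=g)
        for C in (0.1, 1.0, 10.0)
        for g in (0.01, 0.1, 1.0)
    ]
    return [
        AlgorithmGrid(
            "naive_bayes",
            [c("gnb_smooth1e-9", var_smoothing=1e-9), c("gnb_smooth1e-7", var_smoothing=1e-7)],
            scaling=False,
        ),
        AlgorithmGrid(
            "random_forest",
            [
                c("rf_100_sqrt", n_estimators=100, max_features="sqrt"),
                c("rf_100_depth6", n_estimators=100, max_depth=6, max_features="sqrt"),
            ],
            scaling=False,
        ),
        AlgorithmGrid(
            "logistic_regression",
            [c("lr_C0.1", C=0.1), c("lr_C1", C=1.0), c("lr_C10", C=10.0)],
            scaling=True,
        ),
        AlgorithmGrid("svm", svm_cfgs, scaling=True),
        AlgorithmGrid(
            "mlp",
            [
                c("mlp_h16", hidden_layer_sizes=(16,), alpha=1e-3),
                c("mlp_h32", hidden_layer_sizes=(32,), alpha=1e-4),
            ],
            scaling=True,
        ),
    ]


def _build_estimator(family: str, config: Configuration, random_state: int):
    params = config.as_dict()
    if family == "naive_bayes":
        return GaussianNB(**params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=random_state, n_jobs=1, **params)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, **params)
    if family == "svm":
        params.setdefault("kernel", "rbf")
        return SVC(random_state=random_state, **params)
    if family == "mlp":
        hidden = params.pop("hidden_layer_sizes", (16,))
        if isinstance(hidden, list):
            hidden = tuple(hidden)
        # lbfgs is fast and reproducible on small tabular problems; the cap
        # trades exact convergence for screening throughput
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            solver="lbfgs",
            max_iter=250,
            random_state=random_state,
            **params,
        )
    raise ConfigError(f"unknown family {family!r}")


def _config_random_state(seed: int, family: str, config_name: str) -> int:
    """Stable per-configuration RNG seed, independent of execution order."""
    h = zlib.crc32(f"{seed}:{family}:{config_name}".encode())
    return int(h % (2**31 - 1))


def _oof_scores(estimator, scaling: bool, X: np.ndarray, y: np.ndarray, plan: FoldPlan) -> np.ndarray:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    scores = np.empty(len(y), dtype=float)
    for train, test in plan.splits():
        model = Pipeline([("scale", StandardScaler()), ("clf", estimator)]) if scaling else estimator
        model = clone(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[train], y[train])
        if hasattr(model, "predict_proba"):
            scores[test] = model.predict_proba(X[test])[:, 1]
        else:
            scores[test] = model.decision_function(X[test])
    return scores


def run_meta_classification(
    matrix: FeatureMatrix,
    grids: Optional[Sequence[AlgorithmGrid]] = None,
    fold_plan: Optional[FoldPlan] = None,
    seed: int = 0,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    k: int = 10,
) -> ClassificationIndication:
    """Run every configuration of every family and consolidate best AUCs.

    Each configuration is fit on k-1 folds and scored on the held-out fold;
    the pooled out-of-fold scores give one AUC per configuration.  Numeric
    standardization for the families that need it happens inside each
    training fold, so no information leaks across the fold boundary.
    Configurations are independent tasks: each draws its random state from
    ``(seed, family, configuration name)``, so the consolidated result does
    not depend on execution order or concurrency.  A configuration that
    raises is recorded as failed and the run continues; only if everything
    fails is an error raised.
    """
    grids = list(grids) if grids is not None else default_grids()
    if fold_plan is None:
        fold_plan = make_fold_plan(matrix.label, k=k, seed=seed)
    X, y = matrix.values, matrix.label

    families: dict[str, FamilyResult] = {}
    any_success = False
    for grid in grids:
        result = FamilyResult(grid.family, best_auc=None, best_configuration=None)
        for config in grid.configurations:
            rs = _config_random_state(seed, grid.family, config.name)
            try:
                est = _build_estimator(grid.family, config, rs)
                scores = _oof_scores(est, grid.scaling, X, y, fold_plan)
                auc = compute_auc(scores, y)
            except Exception as exc:  # noqa: BLE001 - a failing config must not stop the run
                logger.warning("configuration %s/%s failed: %s", grid.family, config.name, exc)
                result.failures[config.name] = str(exc)
                result.per_configuration[config.name] = None
                continue
            any_success = True
            result.per_configuration[config.name] = auc
            if result.best_auc is None or auc > result.best_auc:
                result.best_auc = auc
                result.best_configuration = config.name
        families[grid.family] = result
    if not any_success:
        raise ContractError("all configurations of all families failed")

    best_family = max(
        (f for f in families.values() if f.best_auc is not None), key=lambda f: f.best_auc
    )
    verdict = interpret_indication(best_family.best_auc, thresholds)
    provenance = {
        "features": matrix.feature_names,
        "n": matrix.n,
        "p": matrix.p,
        "seed": seed,
        "k": fold_plan.k,
        "fold_seed": fold_plan.seed,
        "positive_class": matrix.positive_class,
        "auc_pooling": "pooled out-of-fold scores, one AUC per configuration",
    }
    return ClassificationIndication(
        families=families,
        overall_best=float(best_family.best_auc),
        overall_family=best_family.family,
        verdict=verdict,
        thresholds=thresholds,
        provenance=provenance,
    )


def interpret_indication(
    indication: "ClassificationIndication | float",
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> str:
    """Map an overall best AUC to a qualitative verdict.

    Below ``t_low`` the assumed influence is not measurable in the data
    (an AUC close to 0.5 will rarely be tuned up to a satisfying model);
    at or above ``t_high`` the indication is strong; in between, weak.
    """
    t_low, t_high = thresholds
    if t_low >= t_high:
        raise ConfigError(f"thresholds must satisfy t_low < t_high, got {thresholds}")
    best = indication.overall_best if isinstance(indication, ClassificationIndication) else float(indication)
    if best < t_low:
        return "no_measurable_influence"
    if best >= t_high:
        return "strong_indication"
    return "weak_indication"
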