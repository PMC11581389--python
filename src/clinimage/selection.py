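"""Feature selection and linear-SVM classification on deep feature vectors.

Selection is a two-stage screen applied inside cross-validation: (1) a
two-sided Wilcoxon rank-sum test per feature keeps features with p < 0.005
(raw, no multiplicity adjustment); (2) a Random Forest ranks the survivors by
Gini (impurity-decrease) importance and keeps those strictly above the median
importance. Stability selection repeats the screen on the training portion of
every fold of every cross-validation round and retains only the intersection
— features deemed important in all 100 cycles. A linear SVM on standardized
stable features yields signed-distance decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SelectionResult",
    "CVScheme",
    "TrainedModel",
    "EmptySelectionError",
    "univariate_filter",
    "gini_select",
    "stable_features",
    "fallback_indices",
    "train_svm",
    "decision_scores",
]

DEFAULT_P_THRESHOLD = 0.005
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt"}


class EmptySelectionError(RuntimeError):
    """No feature survived selection; carries per-cycle diagnostics."""

    def __init__(self, message: str, per_cycle_counts: list[int] | None = None):
        super().__init__(message)
        self.per_cycle_counts = per_cycle_counts or []


@dataclass
class SelectionResult:
    """Outcome of one filter + Gini-importance selection cycle."""

    p_values: np.ndarray  # per input feature
    p_threshold: float
    importances: np.ndarray  # per feature passing the filter
    selected_mask: np.ndarray  # bool per input feature
    provenance: tuple[int, int] | None = None  # (round, fold) inside CV

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected_mask)


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme for stability selection."""

    n_folds: int = 10
    n_rounds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 1 or self.n_rounds < 1:
            raise ValueError("n_folds and n_rounds must be >= 1")

    @property
    def n_cycles(self) -> int:
        return self.n_folds * self.n_rounds


def univariate_filter(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p-value per column and the mask ``p < threshold``.

    Exact p-values for tiny tie-free groups, normal approximation with tie
    correction otherwise (scipy's Mann-Whitney U, identical test). Constant
    columns get p = 1.
    """
    x = np.asarray(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    a, b = x[y == classes[1]], x[y == classes[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(a, b, axis=0, method="auto", alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.all(x == x[0], axis=0)
    p[constant | ~np.isfinite(p)] = 1.0
    return p, p < p_threshold


def gini_select(
    filtered_features: np.ndarray,
    labels: np.ndarray,
    rf_params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gini importances of the filtered features and the strict above-median mask.

    Returns ``(importances, mask)`` over the filtered feature set. With all
    importances equal the strict inequality selects nothing; with distinct
    importances exactly ``floor(k/2)`` features survive.
    """
    x = np.asarray(filtered_features)
    if x.shape[1] < 2:
        raise EmptySelectionError("need at least 2 filtered features to rank")
    params = dict(DEFAULT_RF_PARAMS)
    params.update(rf_params or {})
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    forest.fit(x, labels)
    importances = forest.feature_importances_
    return importances, importances > np.median(importances)


def _select_once(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float,
    rf_params: dict | None,
    seed: int,
    provenance: tuple[int, int] | None = None,
) -> SelectionResult:
    p_values, filter_mask = univariate_filter(features, labels, p_threshold)
    filtered_idx = np.flatnonzero(filter_mask)
    selected_mask = np.zeros(features.shape[1], dtype=bool)
    if filtered_idx.size < 2:
        return SelectionResult(p_values, p_threshold, np.empty(0), selected_mask,
                               provenance)
    importances, gini_mask = gini_select(
        features[:, filtered_idx], labels, rf_params, seed
    )
    selected_mask[filtered_idx[gini_mask]] = True
    return SelectionResult(p_values, p_threshold, importances, selected_mask,
                           provenance)


def stable_features(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: CVScheme = CVScheme(),
    p_threshold: float = DEFAULT_P_THRESHOLD,
    rf_params: dict | None = None,
) -> np.ndarray:
    """Indices of features selected in every cycle of every round.

    Each cycle fits the filter + Gini screen on the fold-training portion of a
    stratified k-fold partition; the final set is the intersection over all
    ``n_folds * n_rounds`` cycles. A degenerate 1-fold/1-round scheme equals a
    single selection pass on the full training set.
    """
    x = np.asarray(features)
    y = np.asarray(labels)
    if scheme.n_folds == 1:
        cycles: list[list[np.ndarray]] = [
            [np.arange(len(y))] for _ in range(scheme.n_rounds)
        ]
    else:
        cycles = []
        for r in range(scheme.n_rounds):
            splitter = StratifiedKFold(
                n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + r
            )
            cycles.append([tr for tr, _ in splitter.split(x, y)])

    stable: np.ndarray | None = None
    counts: list[int] = []
    for r, folds in enumerate(cycles):
        for f, train_rows in enumerate(folds):
            result = _select_once(
                x[train_rows], y[train_rows], p_threshold, rf_params,
                seed=scheme.seed + 1000 * r + f, provenance=(r, f),
            )
            counts.append(int(result.selected_mask.sum()))
            sel = set(result.selected_indices.tolist())
            stable = sel if stable is None else stable & sel
            if not stable:
                break
        if stable is not None and not stable:
            break
    if not stable:
        raise EmptySelectionError(
            f"stability intersection empty after {len(counts)} cycles "
            f"(per-cycle selected counts: {counts})",
            per_cycle_counts=counts,
        )
    return np.array(sorted(stable), dtype=int)


def fallback_indices(
    p_values: np.ndarray, p_threshold: float = DEFAULT_P_THRESHOLD, k: int = 50
) -> np.ndarray:
    """Usable feature set when the selection screen comes up (nearly) empty.

    Returns the filter-passing columns when at least two pass; otherwise the
    ``k`` smallest-p non-degenerate columns (constant columns carry p = 1 and
    are never used). An all-degenerate matrix yields an empty set, which
    callers treat as "no model" (chance-level scores).
    """
    idx = np.flatnonzero(p_values < p_threshold)
    if idx.size >= 2:
        return idx
    usable = np.flatnonzero(p_values < 1.0)
    if usable.size == 0:
        return np.empty(0, dtype=int)
    order = usable[np.argsort(p_values[usable], kind="stable")]
    return np.sort(order[: min(k, order.size)])


@dataclass
class TrainedModel:
    """Linear SVM over standardized stable features."""

    svm: SVC
    scaler: StandardScaler
    selected_indices: np.ndarray
    C: float = 1.0

    @property
    def weights(self) -> np.ndarray:
        return self.svm.coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svm.intercept_[0])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    selected_indices: np.ndarray | None = None,
    C: float = 1.0,
) -> TrainedModel:
    """Standardize the (stable-)selected features and fit a linear SVM."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("cannot train on a single class")
    idx = (
        np.arange(features.shape[1])
        if selected_indices is None
        else np.asarray(selected_indices, dtype=int)
    )
    if idx.size == 0:
        raise EmptySelectionError("no selected features to train on")
    scaler = StandardScaler().fit(features[:, idx])
    svm = SVC(kernel="linear", C=C)
    svm.fit(scaler.transform(features[:, idx]), y)
    return TrainedModel(svm=svm, scaler=scaler, selected_indices=idx, C=C)


def decision_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Signed distances to the hyperplane (positive side = IDE class)."""
    z = model.scaler.transform(features[:, model.selected_indices])
    return model.svm.decision_function(z)
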