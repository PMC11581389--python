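"""Performance evaluation: ROC/AUC, Youden operating point, permutation test.

The operating threshold maximises Youden's J = sensitivity + specificity - 1
over all midpoints between distinct scores (plus the two trivial thresholds);
accuracy, sensitivity, specificity and precision are reported at that point.
Label-permutation significance reports both add-one estimators: the standard
convention counts permuted AUCs >= observed, while the count of permuted AUCs
<= observed is also reported (a well-separated model drives the latter to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "PermutationResult",
    "roc_auc",
    "youden_point",
    "evaluate_scores",
    "permutation_test",
    "rescore_auc_fn",
    "patient_spearman",
    "summarize_cv",
]

METRICS = ("auc", "accuracy", "sensitivity", "specificity", "precision")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC with half-credit ties; equals U / (n1 * n0)."""
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("both classes required for AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _confusion(scores: np.ndarray, labels: np.ndarray,
               threshold: float) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, tn, fn


def youden_point(scores: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Threshold maximising J and the metrics at that operating point.

    Candidate thresholds are midpoints between consecutive distinct scores
    plus -inf/+inf; ``score >= threshold`` predicts positive; ties in J break
    to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best_t, best_j, best_counts = None, -np.inf, None
    for t in candidates:
        tp, fp, tn, fn = _confusion(s, y, t)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j, best_counts = t, j, (tp, fp, tn, fn)
    tp, fp, tn, fn = best_counts
    n = tp + fp + tn + fn
    metrics = {
        "youden_j": best_j,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
    }
    return float(best_t), metrics


@dataclass
class EvaluationReport:
    """AUC plus Youden-point metrics, recomputable from the confusion counts."""

    auc: float
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    n_pos: int
    n_neg: int
    confusion: tuple[int, int, int, int]  # (tp, fp, tn, fn)
    cv_distributions: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "confusion": list(self.confusion),
            "cv_distributions": {
                k: list(v) for k, v in self.cv_distributions.items()
            },
        }


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """Full report: AUC plus metrics at the Youden-optimal threshold."""
    y = np.asarray(labels)
    threshold, m = youden_point(scores, y)
    return EvaluationReport(
        auc=roc_auc(scores, y),
        threshold=threshold,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        precision=m["precision"],
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
        confusion=(m["tp"], m["fp"], m["tn"], m["fn"]),
    )


@dataclass
class PermutationResult:
    """Label-permutation null distribution and both add-one p-values."""

    n_permutations: int
    null_aucs: np.ndarray
    observed_auc: float
    p_value_standard: float  # (#{null >= observed} + 1) / (N + 1)
    p_value_paper: float  # (#{null <= observed} + 1) / (N + 1)
    seed: int


def permutation_test(
    auc_of_labels: Callable[[np.ndarray], float],
    labels: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permutation significance of an AUC-producing procedure.

    ``auc_of_labels`` maps a (possibly permuted) label vector to the AUC the
    procedure achieves with it; with a refitting closure this is the honest
    full null, with :func:`rescore_auc_fn` it is the fast fixed-model null.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels)
    observed = float(auc_of_labels(y))
    rng = np.random.default_rng(seed)
    null = np.array(
        [float(auc_of_labels(rng.permutation(y))) for _ in range(n_permutations)]
    )
    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    return PermutationResult(
        n_permutations=n_permutations,
        null_aucs=null,
        observed_auc=observed,
        p_value_standard=(n_ge + 1) / (n_permutations + 1),
        p_value_paper=(n_le + 1) / (n_permutations + 1),
        seed=seed,
    )


def rescore_auc_fn(scores: np.ndarray) -> Callable[[np.ndarray], float]:
    """Fixed-model permutation closure: scores stay frozen, labels permute."""
    s = np.asarray(scores, dtype=float)
    return lambda y: roc_auc(s, y)


def patient_spearman(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and p-value between every pair of patients' feature rows.

    Returns symmetric ``n x n`` matrices with unit diagonal; pairs involving a
    constant patient vector are NaN (flagged, not an error). P-values use the
    standard t approximation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2) x p matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("impute missing values before correlation")
    m = x.shape[1]
    ranks = stats.rankdata(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)  # Pearson on ranks == Spearman, NaN if constant
        t = rho * np.sqrt(np.clip((m - 2) / (1.0 - rho**2), 0, np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
        p[np.abs(rho) >= 1.0] = 0.0  # |rho|=1: t diverges, p -> 0
    defined = np.isfinite(np.diag(rho))
    ii = np.where(defined)[0]
    rho[ii, ii] = 1.0
    p[ii, ii] = 0.0
    p[~np.isfinite(rho)] = np.nan
    return rho, p


def summarize_cv(
    per_fold: list[EvaluationReport],
) -> dict[str, tuple[float, float, float]]:
    """Median and quartiles (q1, median, q3 order: (median, q1, q3)) of each
    metric across fold evaluations."""
    if not per_fold:
        raise ValueError("no fold reports to summarize")
    out: dict[str, tuple[float, float, float]] = {}
    for metric in METRICS:
        vals = np.array([getattr(r, metric) for r in per_fold], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[metric] = (float(med), float(q1), float(q3))
    return out
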