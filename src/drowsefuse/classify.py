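"""PUK-kernel SVM classification under leave-one-subject-out CV.

The Pearson VII function-based universal kernel (PUK),

    k(x, y) = 1 / [1 + (2 * ||x - y|| * sqrt(2^(1/omega) - 1) / sigma)^2]^omega,

behaves like a generalized RBF whose tail weight is controlled by omega.
Features are min-max scaled to [0, 1] using training-fold statistics only.
The classification instance is one minute (5 per state per subject), so an
11-subject study pools to 110 instances - 55 alert and 55 drowsy - in the
cross-validated confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .errors import EmptyDataError, ParameterError

ALERT, DROWSY = "alert", "drowsy"


@dataclass(frozen=True)
class KernelParams:
    """PUK shape parameters; both must be positive."""

    omega: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if not (self.omega > 0 and self.sigma > 0):
            raise ParameterError("omega and sigma must be positive")


def puk_gram(X: np.ndarray, Y: np.ndarray,
             params: KernelParams = KernelParams()) -> np.ndarray:
    """PUK Gram matrix between the rows of X and Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ParameterError("non-finite values in kernel inputs")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    c = 4.0 * (2.0 ** (1.0 / params.omega) - 1.0) / params.sigma ** 2
    return (1.0 + c * d2) ** (-params.omega)


def puk_kernel(x: np.ndarray, y: np.ndarray,
               params: KernelParams = KernelParams()) -> float:
    """PUK similarity of two feature vectors; 1 at zero distance, strictly
    decreasing in ||x - y||."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ParameterError("vectors must have equal length")
    return float(puk_gram(x[np.newaxis], y[np.newaxis], params)[0, 0])


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Pooled 2x2 confusion counts with fixed class order (alert, drowsy):
    tp = alert classified alert, fn = alert -> drowsy, fp = drowsy -> alert,
    tn = drowsy -> drowsy."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or int(v) != v:
                raise ParameterError("confusion counts must be non-negative "
                                     "integers")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=int)

    @classmethod
    def from_rows(cls, rows) -> "ConfusionMatrix2x2":
        """Build from ``[[tp, fn], [fp, tn]]`` (actual x predicted)."""
        (tp, fn), (fp, tn) = rows
        return cls(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))


def accuracy(cm: ConfusionMatrix2x2) -> float:
    """Exact pooled accuracy percentage, 100 * (TP + TN) / total."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    return float(Fraction(100 * (cm.tp + cm.tn), cm.total))


def accuracy_display(cm: ConfusionMatrix2x2) -> str:
    """Accuracy as printed in performance tables: truncated (not rounded)
    to two decimals, e.g. 89/110 -> '80.90'."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    scaled = (10_000 * (cm.tp + cm.tn)) // cm.total
    return f"{scaled // 100}.{scaled % 100:02d}"


@dataclass
class EvaluationReport:
    """One classifier configuration's pooled LOSO results."""

    label: str
    confusion: ConfusionMatrix2x2
    fold_accuracies: dict  # subject_id -> per-fold accuracy (%)
    n_features: int
    params: KernelParams = field(default_factory=KernelParams)
    C: float = 1.0

    @property
    def accuracy_pct(self) -> float:
        return accuracy(self.confusion)

    @property
    def accuracy_str(self) -> str:
        return accuracy_display(self.confusion)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "confusion": {
                "tp": self.confusion.tp, "fn": self.confusion.fn,
                "fp": self.confusion.fp, "tn": self.confusion.tn,
            },
            "accuracy_pct": self.accuracy_pct,
            "accuracy_display": self.accuracy_str,
            "fold_accuracies": self.fold_accuracies,
            "n_features": self.n_features,
            "svm": {"C": self.C, "omega": self.params.omega,
                    "sigma": self.params.sigma},
        }


class PukSvm:
    """Soft-margin SVM with the PUK kernel and fold-local min-max scaling."""

    def __init__(self, params: KernelParams = KernelParams(), C: float = 1.0):
        if not C > 0:
            raise ParameterError("C must be positive")
        self.params = params
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PukSvm":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ParameterError("X must be (n_instances, n_features) with "
                                 "matching labels")
        if not np.isfinite(X).all():
            raise ParameterError("non-finite feature values")
        if np.unique(y).size < 2:
            raise ParameterError("single-class training fold")
        self._lo = X.min(axis=0)
        span = X.max(axis=0) - self._lo
        span[span == 0] = 1.0  # constant feature -> maps to 0
        self._span = span
        Xs = (X - self._lo) / self._span
        self._svc = SVC(
            kernel=lambda A, B: puk_gram(A, B, self.params), C=self.C)
        self._svc.fit(Xs, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self._lo) / self._span
        return self._svc.predict(Xs)


def fit_svm(X: np.ndarray, y: np.ndarray,
            params: KernelParams = KernelParams(), C: float = 1.0) -> PukSvm:
    """Train a PUK-kernel SVM; features are min-max scaled to [0, 1] with
    training statistics only, and the same transform is applied at
    prediction time."""
    return PukSvm(params=params, C=C).fit(X, y)


def loso_cv(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
            params: KernelParams = KernelParams(), C: float = 1.0,
            label: str = "") -> EvaluationReport:
    """Leave-one-subject-out cross-validation.

    One fold per subject: the held-out subject's minute-instances are
    predicted by a model trained on everyone else; predictions are pooled
    into a single confusion matrix.  With 11 subjects and 5 minutes per
    state the pooled total is 110 with 55/55 row sums.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    if X.shape[0] != y.shape[0] or y.shape[0] != subjects.shape[0]:
        raise ParameterError("X, y, subjects must align")
    if X.size == 0:
        raise EmptyDataError("no instances to classify")
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ParameterError("leave-one-subject-out needs >= 2 subjects")

    tp = fn = fp = tn = 0
    fold_acc = {}
    for held in uniq:
        test = subjects == held
        train = ~test
        try:
            model = fit_svm(X[train], y[train], params=params, C=C)
        except ParameterError as exc:
            raise ParameterError(f"fold {held!r}: {exc}") from exc
        pred = model.predict(X[test])
        truth = y[test]
        tp += int(np.sum((truth == ALERT) & (pred == ALERT)))
        fn += int(np.sum((truth == ALERT) & (pred == DROWSY)))
        fp += int(np.sum((truth == DROWSY) & (pred == ALERT)))
        tn += int(np.sum((truth == DROWSY) & (pred == DROWSY)))
        fold_acc[str(held)] = float(100.0 * np.mean(pred == truth))

    return EvaluationReport(
        label=label, confusion=ConfusionMatrix2x2(tp, fn, fp, tn),
        fold_accuracies=fold_acc, n_features=X.shape[1],
        params=params, C=C,
    )


# ---------------------------------------------------------------------------
# Instance matrices from the tidy feature table
# ---------------------------------------------------------------------------

def instance_matrix(features: pd.DataFrame,
                    selected: list[tuple[str, str]]):
    """Pivot selected (channel, feature) pairs into per-minute instances.

    Returns ``(X, y, subjects, columns)`` where each row is one
    subject-state-minute.  Instances missing any selected feature are
    dropped (flagged minutes)."""
    if not selected:
        raise EmptyDataError("no features selected")
    key = pd.MultiIndex.from_tuples(selected)
    wide = features.pivot_table(
        index=["subject_id", "state", "minute"],
        columns=["channel", "feature"], values="value",
    )
    missing = [c for c in key if c not in wide.columns]
    if missing:
        raise ParameterError(f"features absent from table: {missing}")
    wide = wide[key].dropna()
    y = wide.index.get_level_values("state").to_numpy()
    subjects = wide.index.get_level_values("subject_id").to_numpy()
    return wide.to_numpy(), y, subjects, list(wide.columns)


def channel_reduction(
    features: pd.DataFrame,
    selection_pairs: list[tuple[str, str]],
    candidate_channels: list[str],
    params: KernelParams = KernelParams(),
    C: float = 1.0,
    max_subset_size: int = 2,
    include_ecg: bool = True,
) -> pd.DataFrame:
    """Evaluate EEG channel subsets (plus the ECG features) under LOSO CV.

    Each subset of ``candidate_channels`` up to ``max_subset_size`` is
    combined with the significant ECG features and scored with
    :func:`loso_cv`.  Subsets whose channels carry no significant EEG
    feature fall back to ECG-only and are flagged.  The ranking is sorted
    by accuracy (descending), ties broken by fewer channels then
    lexicographic label order.
    """
    if not candidate_channels:
        raise ParameterError("candidate channel list is empty")
    ecg_feats = [p for p in selection_pairs if p[0] == "ECG"] \
        if include_ecg else []
    rows = []
    for size in range(1, max_subset_size + 1):
        for subset in combinations(sorted(candidate_channels), size):
            eeg_feats = [p for p in selection_pairs if p[0] in subset]
            flagged = len(eeg_feats) == 0
            feats = eeg_feats + ecg_feats
            if not feats:
                continue
            X, y, subjects, _ = instance_matrix(features, feats)
            rep = loso_cv(X, y, subjects, params=params, C=C,
                          label="+".join(subset) + ("+ECG" if ecg_feats
                                                   else ""))
            rows.append({
                "channels": ",".join(subset),
                "n_channels": size,
                "n_features": len(feats),
                "accuracy_pct": rep.accuracy_pct,
                "accuracy_display": rep.accuracy_str,
                "ecg_included": bool(ecg_feats),
                "no_eeg_features": flagged,
            })
    columns = ["channels", "n_channels", "n_features", "accuracy_pct",
               "accuracy_display", "ecg_included", "no_eeg_features"]
    table = pd.DataFrame(rows, columns=columns)
    if table.empty:
        return table
    table = table.sort_values(
        by=["accuracy_pct", "n_channels", "channels"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    return table
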