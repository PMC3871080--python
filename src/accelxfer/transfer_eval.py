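"""Cross-device activity-type recognition transfer.

Stage 3 of the pipeline: train a random-forest activity classifier on one
device's feature table and evaluate it on the same or the other device's
table, under leave-one-subject-out (LOSO) cross-validation.  "Leave one out"
is implemented at the subject level: window-level hold-out would leak
same-bout windows between training and test folds and inflate every
accuracy.  For cross-device cells the held-out subject is removed from BOTH
tables (train on device A minus subject s, predict device B's subject s), so
same-device and cross-device accuracies are computed on identical folds and
are directly comparable.

Accuracies are reported in percent to one decimal; overall differences in
the proportion of correct predictions are compared with a pooled
two-proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier

from .signal_core import COARSE_LABELS
from .features import TD_COLUMNS, FD_COLUMNS

_META_COLS = ("subject_id", "device_id", "activity", "window_index")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier configuration for the transfer evaluation."""

    feature_set: str = "TD"
    classifier: str = "random_forest"
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError(f"n_trees must be >= 10, got {self.n_trees}")
        if self.feature_set not in ("TD", "FD"):
            raise ValueError(f"feature_set must be 'TD' or 'FD', got {self.feature_set!r}")
        if self.classifier != "random_forest":
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class ConfusionMatrix:
    """Confusion counts (rows = truth, columns = prediction) with recalls."""

    labels: tuple[str, ...]
    counts: np.ndarray
    per_class_recall: dict[str, float]
    overall_accuracy: float

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df["pct_correct"] = [self.per_class_recall[l] for l in self.labels]
        return df


@dataclass
class TransferResult:
    """Accuracy of one (training device, prediction device, feature set) cell."""

    train_device: str
    test_device: str
    feature_set: str
    confusion: ConfusionMatrix
    accuracy: float
    n_correct: int
    n_total: int


def confusion_summary(
    truth, predicted, labels: tuple[str, ...] = COARSE_LABELS
) -> ConfusionMatrix:
    """Build a confusion matrix with per-class recall and overall accuracy.

    Recalls and accuracy are percentages rounded to one decimal.  Any label
    outside the vocabulary raises.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValueError("truth and predicted must have equal length >= 1")
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in idx or p not in idx:
            raise ValueError(f"label outside vocabulary {labels}: {t!r} / {p!r}")
        counts[idx[t], idx[p]] += 1
    recalls = {}
    for l, i in idx.items():
        row = counts[i].sum()
        recalls[l] = float(round(100.0 * counts[i, i] / row, 1)) if row else float("nan")
    overall = float(round(100.0 * np.trace(counts) / counts.sum(), 1))
    return ConfusionMatrix(
        labels=tuple(labels),
        counts=counts,
        per_class_recall=recalls,
        overall_accuracy=overall,
    )


def _feature_matrix(table: pd.DataFrame, feature_set: str) -> np.ndarray:
    cols = TD_COLUMNS if feature_set == "TD" else FD_COLUMNS
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(
            f"table lacks {feature_set} feature columns {missing}; "
            f"has {list(table.columns)}"
        )
    return table[list(cols)].to_numpy(dtype=float)


def loso_transfer(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    spec: ModelSpec,
) -> TransferResult:
    """Leave-one-subject-out transfer accuracy.

    For each subject s, the forest is fit on ``train_table`` without s and
    applied to ``test_table`` rows of s; all held-out predictions are pooled
    into one confusion matrix.  Deterministic given ``spec.seed``.
    """
    for name, tbl in (("train", train_table), ("test", test_table)):
        if tbl.attrs.get("feature_set", spec.feature_set) != spec.feature_set:
            raise ValueError(
                f"{name} table feature_set {tbl.attrs['feature_set']!r} "
                f"!= spec {spec.feature_set!r}"
            )
    subjects = sorted(set(train_table["subject_id"]))
    if len(subjects) < 2:
        raise ValueError(f"need >= 2 subjects, got {subjects}")
    if sorted(set(test_table["subject_id"])) != subjects:
        raise ValueError("train and test tables must cover the same subjects")
    truths: list[str] = []
    preds: list[str] = []
    for s in subjects:
        fit_rows = train_table[train_table["subject_id"] != s]
        eval_rows = test_table[test_table["subject_id"] == s]
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt",
            random_state=spec.seed,
            n_jobs=1,
        )
        clf.fit(_feature_matrix(fit_rows, spec.feature_set), fit_rows["activity"])
        preds.extend(clf.predict(_feature_matrix(eval_rows, spec.feature_set)))
        truths.extend(eval_rows["activity"])
    cm = confusion_summary(truths, preds)
    return TransferResult(
        train_device=str(train_table["device_id"].iloc[0]),
        test_device=str(test_table["device_id"].iloc[0]),
        feature_set=spec.feature_set,
        confusion=cm,
        accuracy=cm.overall_accuracy,
        n_correct=cm.n_correct,
        n_total=cm.n_total,
    )


def transfer_grid(
    tables: dict[tuple[str, str], pd.DataFrame],
    device_a: str,
    device_b: str,
    spec: ModelSpec = ModelSpec(),
    feature_sets: tuple[str, ...] = ("FD", "TD"),
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], TransferResult]]:
    """All {FD, TD} x {A->A, A->B, B->B, B->A} transfer cells.

    ``tables`` maps ``(device_id, feature_set)`` to a feature table.  All
    cells share the classifier seed so same- and cross-device cells differ
    only through the prediction data.  Returns a tidy summary frame plus the
    per-cell results keyed by (feature_set, train_device, test_device).
    """
    results: dict[tuple[str, str, str], TransferResult] = {}
    rows = []
    for fset in feature_sets:
        for train_dev, test_dev in (
            (device_a, device_a),
            (device_a, device_b),
            (device_b, device_b),
            (device_b, device_a),
        ):
            key_tr, key_te = (train_dev, fset), (test_dev, fset)
            if key_tr not in tables or key_te not in tables:
                raise ValueError(f"missing feature table for {key_tr} or {key_te}")
            res = loso_transfer(
                tables[key_tr],
                tables[key_te],
                ModelSpec(feature_set=fset, classifier=spec.classifier,
                          n_trees=spec.n_trees, seed=spec.seed),
            )
            results[(fset, train_dev, test_dev)] = res
            rows.append(
                {
                    "feature_set": fset,
                    "train_device": train_dev,
                    "test_device": test_dev,
                    "accuracy_pct": res.accuracy,
                    "n_correct": res.n_correct,
                    "n_total": res.n_total,
                }
            )
    return pd.DataFrame(rows), results


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test for a difference in accuracy.

    z = (k1/n1 - k2/n2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with the pooled
    proportion p = (k1+k2)/(n1+n2); the p-value is two-sided normal.  When
    the pooled proportion is 0 or 1 there is no evidence either way and
    (z, p) = (0, 1) by convention.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), min(p, 1.0)
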