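"""Train-on-synthetic / test-on-real (TSTR) evaluation harness.

The predictive model is an L2-regularised logistic regression fitted on
features standardised to the training source (the scaler is fitted on the
training rows only and applied to whatever rows are scored, so no test-set
leakage).  The TSTR grid mirrors a three-column layout — (train real, test
real), (train synthetic, test synthetic), (train synthetic, test real) —
with training-split, 5-fold cross-validated and 20%-holdout metrics in each
cell; the real holdout is computed once and shared by the first and third
cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, SchemaError, StratificationError

__all__ = [
    "LabeledMatrix",
    "EvalResult",
    "TSTRResult",
    "split_holdout",
    "train_l2_logistic",
    "evaluate_metrics",
    "cross_validate",
    "run_tstr_grid",
]

METRICS = ("accuracy", "precision", "recall", "f1", "auroc")


@dataclass
class LabeledMatrix:
    """Numeric/binary feature matrix with a binary outcome per row."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != self.labels.size:
            raise SchemaError("features and labels differ in length")
        present = set(np.unique(self.labels))
        if not present <= {0, 1}:
            raise ConfigError(f"labels must be binary 0/1, got {sorted(present)}")
        if present != {0, 1}:
            raise ConfigError("both outcome classes must be present")
        if not all(pd.api.types.is_numeric_dtype(self.features[c]) for c in self.features):
            raise ConfigError("all features must be numeric or binary")

    def subset(self, idx) -> "LabeledMatrix":
        return LabeledMatrix(
            self.features.iloc[idx].reset_index(drop=True), self.labels[np.asarray(idx)]
        )

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    split: str = "test"

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


@dataclass
class TSTRResult:
    """Metric grid keyed by (train source, test source)."""

    cells: dict[tuple[str, str], dict[str, EvalResult]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            f"{tr}->{te}": {split: res.as_dict() for split, res in splits.items()}
            for (tr, te), splits in self.cells.items()
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tr, te), splits in self.cells.items():
            for split, res in splits.items():
                rows.append({"train": tr, "test": te, "split": split, **res.as_dict()})
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def split_holdout(
    data: LabeledMatrix, fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Label-stratified holdout split; disjoint and exhaustive."""
    if not 0 < fraction < 1:
        raise ConfigError("fraction must be in (0, 1)")
    idx = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        idx, test_size=fraction, stratify=data.labels, random_state=seed
    )
    train, test = data.subset(train_idx), data.subset(np.sort(test_idx))
    for part, name in ((train, "train"), (test, "test")):
        if set(np.unique(part.labels)) != {0, 1}:
            raise StratificationError(f"class absent from {name} part after split")
    return train, test


def _make_model(penalty_lambda: float, seed: int) -> Pipeline:
    if penalty_lambda < 0:
        raise ConfigError("penalty must be >= 0")
    C = np.inf if penalty_lambda == 0 else 1.0 / penalty_lambda
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logit",
                LogisticRegression(
                    C=C, solver="lbfgs", max_iter=5000, tol=1e-10, random_state=seed,
                ),
            ),
        ]
    )


def train_l2_logistic(
    train: LabeledMatrix, penalty_lambda: float = 1.0, seed: int = 0
) -> Pipeline:
    """Fit the L2 logistic model on internally standardised features.

    Returns the fitted scaler+classifier pipeline; coefficients live in
    ``model["logit"].coef_`` (on the standardised scale) and the intercept in
    ``model["logit"].intercept_``.
    """
    X = train.features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ConfigError("non-finite feature values")
    model = _make_model(penalty_lambda, seed)
    model.fit(X, train.labels)
    return model


def evaluate_metrics(scores, labels, threshold: float = 0.5, split: str = "test") -> EvalResult:
    """Confusion-matrix metrics at a score threshold plus rank-based AUROC.

    AUROC uses tie mid-ranking (the probability a random case outscores a
    random control, counting ties half).  Single-class labels leave AUROC
    undefined (NaN).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.min() < 0 or scores.max() > 1:
        raise ConfigError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    if np.unique(labels).size < 2:
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, scores))
    return EvalResult(
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        auroc=auroc,
        split=split,
    )


def _score(model: Pipeline, data: LabeledMatrix) -> np.ndarray:
    return model.predict_proba(data.features.to_numpy(dtype=float))[:, 1]


def cross_validate(
    data: LabeledMatrix, k: int = 5, penalty_lambda: float = 1.0, seed: int = 0
) -> EvalResult:
    """Stratified k-fold cross-validation; metrics are the unweighted mean
    over per-fold validation metrics."""
    if k > len(data):
        raise ConfigError(f"k={k} exceeds n={len(data)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_results = []
    for train_idx, val_idx in skf.split(data.features, data.labels):
        model = train_l2_logistic(data.subset(train_idx), penalty_lambda, seed)
        val = data.subset(val_idx)
        fold_results.append(evaluate_metrics(_score(model, val), val.labels, split="cv"))
    means = {m: float(np.mean([getattr(r, m) for r in fold_results])) for m in METRICS}
    return EvalResult(split="cv", **means)


def _evaluate_cell(
    train: LabeledMatrix,
    test: LabeledMatrix,
    penalty_lambda: float,
    seed: int,
) -> dict[str, EvalResult]:
    model = train_l2_logistic(train, penalty_lambda, seed)
    return {
        "train": evaluate_metrics(_score(model, train), train.labels, split="train"),
        "cv": cross_validate(train, 5, penalty_lambda, seed),
        "test": evaluate_metrics(_score(model, test), test.labels, split="test"),
    }


def run_tstr_grid(
    real: LabeledMatrix,
    synth: LabeledMatrix,
    penalty_lambda: float = 1.0,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> TSTRResult:
    """The three-cell TSTR grid.

    Cells: (real, real) trains on the real 80% and tests on the real 20%
    holdout; (synthetic, synthetic) likewise within the synthetic table;
    (synthetic, real) trains on the same synthetic 80% and tests on the
    *same* real holdout rows as the first cell.
    """
    if list(real.features.columns) != list(synth.features.columns):
        raise SchemaError(
            "real and synthetic feature schemas differ: "
            f"{sorted(set(real.features.columns) ^ set(synth.features.columns))}"
        )
    real_train, real_test = split_holdout(real, holdout_fraction, seed)
    synth_train, synth_test = split_holdout(synth, holdout_fraction, seed)

    result = TSTRResult()
    result.cells[("real", "real")] = _evaluate_cell(real_train, real_test, penalty_lambda, seed)
    result.cells[("synthetic", "synthetic")] = _evaluate_cell(
        synth_train, synth_test, penalty_lambda, seed
    )
    synth_model = train_l2_logistic(synth_train, penalty_lambda, seed)
    result.cells[("synthetic", "real")] = {
        "train": evaluate_metrics(
            _score(synth_model, synth_train), synth_train.labels, split="train"
        ),
        "cv": cross_validate(synth_train, 5, penalty_lambda, seed),
        "test": evaluate_metrics(_score(synth_model, real_test), real_test.labels, split="test"),
    }
    return result
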