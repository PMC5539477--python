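"""Activity recognition under leave-one-subject-out cross-validation.

Five input scenarios are supported: (1) movement features only, (2)
movement + all 31 HRV features, (3) movement + the top-k HRV features
selected by a Mann-Whitney U criterion, (4) HRV only, (5) selected HRV
only.  Classes are SI, ST, WK, RU, AS (REST is excluded from recognition).

Each cross-validation fold holds out one subject for testing and one for
validation; the remaining subjects train the scaler, the feature ranking,
and the classifier.  Hyperparameters (SVM box constraint and RBF gamma,
kNN neighbour count) and, in the selected-feature scenarios, the feature
count k are chosen by validation accuracy; ties resolve to the fewest
features and the smallest hyperparameter values.  Nothing derived from the
test subject ever enters training — the scaler and ranking are refit from
the training partition alone in every fold.

Feature selection ranks each HRV parameter by the *larger* of its two
Mann-Whitney p-values for the SI-vs-ST and WK-vs-AS contrasts, ascending:
a useful feature must separate both confusable pairs.  Ties keep the
canonical parameter order.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .activities import Activity, RECOGNITION_ACTIVITIES
from .hrv import HRV_NAMES
from .imu import IMU_NAMES

__all__ = [
    "Fold",
    "loso_folds",
    "ZScaler",
    "zscore_fit_apply",
    "mann_whitney_u",
    "select_hrv_features",
    "PooledLDA",
    "make_classifier",
    "DEFAULT_GRIDS",
    "ScenarioConfig",
    "FoldResult",
    "EvaluationReport",
    "run_loso",
    "confusion_metrics",
    "format_confusion_table",
]

LABELS: tuple[str, ...] = tuple(a.value for a in RECOGNITION_ACTIVITIES)


# -------------------------------------------------------------------- folds

@dataclass(frozen=True)
class Fold:
    test_subject: str
    validation_subject: str | None
    train_subjects: tuple[str, ...]


def loso_folds(subject_ids: "list[str]", validation: bool = True) -> list[Fold]:
    """One fold per subject as test.

    With ``validation`` the validation subject is the next subject in order
    (cyclically) — deterministic and leakage-free; without it (the
    energy-expenditure layout) all remaining subjects train.
    """
    ids = list(subject_ids)
    if len(ids) < (3 if validation else 2):
        raise ValueError("too few subjects for leave-one-subject-out folds")
    folds = []
    for i, test in enumerate(ids):
        if validation:
            val = ids[(i + 1) % len(ids)]
            train = tuple(s for s in ids if s not in (test, val))
        else:
            val = None
            train = tuple(s for s in ids if s != test)
        folds.append(Fold(test_subject=test, validation_subject=val,
                          train_subjects=train))
    return folds


# ------------------------------------------------------------------- scaling

@dataclass
class ZScaler:
    """Per-feature z-normalization with sample SD, fit on training data only.

    Zero-variance features are centred and given unit scale (flagged).
    Flagged-missing feature values (NaN) are ignored when fitting and
    imputed with the training mean (z = 0) on transform."""

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    zero_variance: tuple[int, ...] = ()

    def fit(self, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("scaler needs a 2-D training matrix with >= 2 rows")
        self.mean_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        zero = (sd == 0) | ~np.isfinite(sd)
        self.zero_variance = tuple(np.flatnonzero(zero))
        sd = np.where(zero, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler is not fitted")
        z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return np.nan_to_num(z, nan=0.0)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


def zscore_fit_apply(
    train: np.ndarray, *others: np.ndarray
) -> tuple[tuple[np.ndarray, ...], ZScaler]:
    """Fit a scaler on ``train`` and apply it to train and every other set."""
    scaler = ZScaler().fit(train)
    out = tuple(scaler.transform(a) for a in (train, *others))
    return out, scaler


# ---------------------------------------------------------- feature selection

def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small untied samples (n <= 8 each), otherwise the
    tie-corrected normal approximation.  Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = x.size <= 8 and y.size <= 8
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_hrv_features(train: pd.DataFrame) -> pd.DataFrame:
    """Rank all 31 HRV features by max(p(SI,ST), p(WK,AS)), ascending."""
    groups = {}
    for a in (Activity.SI, Activity.ST, Activity.WK, Activity.AS):
        sub = train[train["activity"] == a.value]
        if sub.empty:
            raise ValueError(f"training data has no samples of class {a.value}")
        groups[a] = sub
    rows = []
    for idx, name in enumerate(HRV_NAMES):
        _, p_si_st = mann_whitney_u(groups[Activity.SI][name].to_numpy(),
                                    groups[Activity.ST][name].to_numpy())
        _, p_wk_as = mann_whitney_u(groups[Activity.WK][name].to_numpy(),
                                    groups[Activity.AS][name].to_numpy())
        rows.append({"feature": name, "p_si_st": p_si_st, "p_wk_as": p_wk_as,
                     "score": max(p_si_st, p_wk_as), "order": idx})
    ranked = pd.DataFrame(rows).sort_values(["score", "order"],
                                            kind="stable")
    return ranked.reset_index(drop=True)


def select_hrv_features(train: pd.DataFrame, k: int) -> list[str]:
    """Top-k HRV feature names under the two-contrast Mann-Whitney ranking."""
    if k < 0 or k > len(HRV_NAMES):
        raise ValueError(f"k must be in [0, {len(HRV_NAMES)}]")
    if k == 0:
        return []
    return rank_hrv_features(train)["feature"].head(k).tolist()


# ---------------------------------------------------------------- classifiers

class PooledLDA:
    """Linear discriminant analysis with pooled within-class covariance.

    Closed form: discriminant_c(x) = x'S^-1 mu_c - mu_c'S^-1 mu_c / 2
    + ln pi_c, with S the pooled sample covariance (a small ridge is added
    for numerical safety on near-singular problems).
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PooledLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = X.shape
        means, priors = [], []
        pooled = np.zeros((p, p))
        for c in self.classes_:
            xc = X[y == c]
            mu = xc.mean(axis=0)
            means.append(mu)
            priors.append(xc.shape[0] / n)
            d = xc - mu
            pooled += d.T @ d
        pooled /= n - self.classes_.size
        pooled += self.ridge * np.trace(pooled) / max(p, 1) * np.eye(p)
        self.means_ = np.asarray(means)
        self.log_priors_ = np.log(priors)
        self.sigma_inv_ = np.linalg.pinv(pooled)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a = self.sigma_inv_ @ self.means_.T          # (p, C)
        b = -0.5 * np.sum(self.means_ @ self.sigma_inv_ * self.means_, axis=1)
        return X @ a + b + self.log_priors_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "lsvm": {"C": tuple(2.0**e for e in range(-5, 16, 2))},
    "rbfsvm": {"C": tuple(2.0**e for e in range(-5, 16, 2)),
               "gamma": tuple(2.0**e for e in range(-15, 4, 2))},
    "knn": {"n_neighbors": (1, 3, 5, 7, 9)},
    "lda": {},
}


def make_classifier(name: str, **hyper):
    if name == "lsvm":
        return SVC(kernel="linear", C=hyper.get("C", 1.0))
    if name == "rbfsvm":
        return SVC(kernel="rbf", C=hyper.get("C", 1.0),
                   gamma=hyper.get("gamma", "scale"))
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=hyper.get("n_neighbors", 3))
    if name == "lda":
        return PooledLDA()
    raise ValueError(f"unknown classifier {name!r}; "
                     "expected lsvm, rbfsvm, knn or lda")


# -------------------------------------------------------------------- driver

@dataclass(frozen=True)
class ScenarioConfig:
    """Recognition scenario and classifier settings."""

    scenario: int = 1
    classifier: str = "lsvm"
    grids: dict = field(default_factory=lambda: DEFAULT_GRIDS)
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError("scenario must be 1..5")
        if self.classifier not in DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def uses_selection(self) -> bool:
        return self.scenario in (3, 5)

    def feature_columns(self, selected: "list[str] | None" = None) -> list[str]:
        imu = list(IMU_NAMES)
        hrv = list(HRV_NAMES)
        sel = list(selected or [])
        return {
            1: imu,
            2: imu + hrv,
            3: imu + sel,
            4: hrv,
            5: sel,
        }[self.scenario]


@dataclass
class FoldResult:
    test_subject: str
    validation_subject: str | None
    chosen_hyper: dict
    selected_features: list[str] | None
    feature_columns: list[str]
    accuracy: float
    confusion: pd.DataFrame


@dataclass
class EvaluationReport:
    config: ScenarioConfig
    folds: list[FoldResult]
    pooled_confusion: pd.DataFrame

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def n_pooled(self) -> int:
        return int(self.pooled_confusion.to_numpy().sum())

    def metrics(self) -> dict:
        return confusion_metrics(self.pooled_confusion)

    def to_json(self) -> str:
        return json.dumps({
            "scenario": self.config.scenario,
            "classifier": self.config.classifier,
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "pooled_accuracy_pct": self.metrics()["accuracy"],
            "n_pooled": self.n_pooled,
            "folds": [
                {
                    "test_subject": f.test_subject,
                    "validation_subject": f.validation_subject,
                    "hyperparameters": f.chosen_hyper,
                    "selected_features": f.selected_features,
                    "accuracy_pct": f.accuracy,
                }
                for f in self.folds
            ],
        }, indent=2)


def _grid_combos(grid: dict[str, tuple]) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, vals))
            for vals in itertools.product(*(sorted(grid[k]) for k in keys))]


def _empty_confusion() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    cm = _empty_confusion()
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


def run_loso(table: pd.DataFrame, config: ScenarioConfig) -> EvaluationReport:
    """Full leave-one-subject-out evaluation of one scenario.

    ``table`` is a per-minute feature table (REST rows, if present, are
    dropped).  Deterministic given the table and config.
    """
    data = table[table["activity"].isin(LABELS)].reset_index(drop=True)
    subjects = list(dict.fromkeys(data["subject_id"]))
    folds = loso_folds(subjects, validation=True)
    combos = _grid_combos(config.grids.get(config.classifier, {}))
    k_values = list(config.k_grid) if config.uses_selection else [None]

    results: list[FoldResult] = []
    pooled = _empty_confusion()
    for fold in folds:
        train = data[data["subject_id"].isin(fold.train_subjects)]
        val = data[data["subject_id"] == fold.validation_subject]
        test = data[data["subject_id"] == fold.test_subject]
        missing = [c for c in LABELS
                   if not (train["activity"] == c).any()]
        if missing or test.empty or val.empty:
            warnings.warn(
                f"fold {fold.test_subject}: missing classes {missing} or "
                "empty partitions; fold excluded"
            )
            continue

        ranking = (rank_hrv_features(train)["feature"].tolist()
                   if config.uses_selection else None)
        best = None  # (val_acc, -k, combo_index, cols, combo, selected)
        for k in k_values:
            selected = ranking[:k] if ranking is not None else None
            cols = config.feature_columns(selected)
            if not cols:
                continue
            (ztr, zva), scaler = zscore_fit_apply(
                train[cols].to_numpy(), val[cols].to_numpy()
            )
            ytr = train["activity"].to_numpy()
            for ci, combo in enumerate(combos):
                clf = make_classifier(config.classifier, **combo)
                clf.fit(ztr, ytr)
                acc = float(np.mean(clf.predict(zva) == val["activity"].to_numpy()))
                key = (acc, -(k or 0), -ci)
                if best is None or key > best[0]:
                    best = (key, cols, combo, selected)
        assert best is not None
        _, cols, combo, selected = best

        (ztr, zte), scaler = zscore_fit_apply(
            train[cols].to_numpy(), test[cols].to_numpy()
        )
        clf = make_classifier(config.classifier, **combo)
        clf.fit(ztr, train["activity"].to_numpy())
        pred = clf.predict(zte)
        y_test = test["activity"].to_numpy()
        cm = _confusion(y_test, pred)
        pooled += cm
        results.append(FoldResult(
            test_subject=fold.test_subject,
            validation_subject=fold.validation_subject,
            chosen_hyper=combo,
            selected_features=selected,
            feature_columns=cols,
            accuracy=100.0 * float(np.mean(pred == y_test)),
            confusion=cm,
        ))
    if not results:
        raise ValueError("no usable folds")
    return EvaluationReport(config=config, folds=results,
                           pooled_confusion=pooled)


# ------------------------------------------------------------------- metrics

def confusion_metrics(counts: "pd.DataFrame | np.ndarray") -> dict:
    """Per-class recall/precision and overall accuracy, in percent.

    A class never predicted has undefined precision (NaN, flagged)."""
    if isinstance(counts, pd.DataFrame):
        cm = counts.to_numpy(dtype=float)
        labels = list(counts.index)
    else:
        cm = np.asarray(counts, dtype=float)
        labels = list(range(cm.shape[0]))
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    recall = {lab: (100.0 * diag[i] / row[i]) if row[i] else float("nan")
              for i, lab in enumerate(labels)}
    precision = {lab: (100.0 * diag[i] / col[i]) if col[i] else float("nan")
                 for i, lab in enumerate(labels)}
    flagged = [lab for i, lab in enumerate(labels) if col[i] == 0]
    return {
        "recall": recall,
        "precision": precision,
        "accuracy": 100.0 * diag.sum() / total,
        "undefined_precision": flagged,
    }


def format_confusion_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Confusion table with a recall (RC) column and precision (PR) row."""
    m = confusion_metrics(counts)
    out = counts.copy().astype(object)
    out["Total"] = counts.sum(axis=1)
    out["RC"] = [round(m["recall"][lab], 2) for lab in counts.index]
    pr = {lab: round(m["precision"][lab], 2) for lab in counts.columns}
    total_row = {**{lab: counts[lab].sum() for lab in counts.columns},
                 "Total": counts.to_numpy().sum(), "RC": ""}
    pr_row = {**pr, "Total": "", "RC": ""}
    out.loc["Total"] = pd.Series(total_row)
    out.loc["PR"] = pd.Series(pr_row)
    return out
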