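"""Energy-expenditure estimation with per-activity-category linear models.

Per-minute EE (kcal/min) is modelled as an ordinary-least-squares linear
function of anthropometrics (height, weight), the four movement features,
and optionally the 31 HRV features.  Four model families are compared:

* Model I   — single model, movement features only (6 candidates)
* Model II  — single model, movement + HRV (37 candidates)
* Model III — activity-specific (static/dynamic), movement only
* Model IV  — activity-specific, movement + HRV

"Activity-specific" fits one model on static minutes (SI, ST, REST) and
one on dynamic minutes (WK, AS, RU); test minutes are routed by their true
category.  Variable selection is backward elimination at p < 0.05 on the
training fold.  Folds are leave-one-subject-out without a validation
subject (all remaining subjects train).  Performance is the per-activity
RMSE per fold, and a balanced two-way fixed-effects ANOVA (factors: data
type and model type, with interaction) compares the four families over the
fold-by-activity RMSE cells.

The OLS coefficients are the normal-equations solution (X'X)^-1 X'Y,
computed via an orthogonal decomposition; standard errors, t-based
p-values and R^2 follow the classical formulas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activities import STATIC_ACTIVITIES, Activity
from .hrv import HRV_NAMES
from .imu import IMU_NAMES
from .recognition import Fold, loso_folds

__all__ = [
    "RegressionModel",
    "EEModelSpec",
    "MODEL_SPECS",
    "ols_fit",
    "select_variables",
    "fit_ee",
    "evaluate_ee",
    "run_ee",
    "EEReport",
    "anova_2x2",
]

ANTHROPOMETRICS = ("height", "weight")
EE_TARGET = "ee_kcal_min"

ACTIVITY_ORDER = ("SI", "ST", "REST", "WK", "AS", "RU")


@dataclass(frozen=True)
class RegressionModel:
    """A fitted linear model: intercept plus named coefficients."""

    variables: tuple[str, ...]
    coef: np.ndarray          # [intercept, beta_1..beta_K]
    stderr: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    resid_var: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.coef.size != len(self.variables) + 1:
            raise ValueError("coefficient count must equal variables + 1")

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def coef_dict(self) -> dict[str, float]:
        out = {"intercept": self.intercept}
        out.update({v: float(b) for v, b in zip(self.variables, self.coef[1:])})
        return out

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = data[list(self.variables)].to_numpy(dtype=float)
        return self.coef[0] + X @ self.coef[1:]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def _screen_aliased(data: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Drop zero-variance and exactly aliased candidate columns (warned)."""
    kept = list(candidates)
    dropped: list[str] = []
    while kept:
        X = data[kept].to_numpy(dtype=float)
        # standardize so the rank tolerance is scale-free
        sd = X.std(axis=0)
        zero = [kept[i] for i in np.flatnonzero(sd == 0)]
        if zero:
            dropped += zero
            kept = [c for c in kept if c not in zero]
            continue
        design = np.column_stack([np.ones(X.shape[0]), X / sd])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            break
        bad = [c for c in _collinear_columns(design, ["intercept"] + kept)
               if c != "intercept"]
        if not bad:
            bad = [kept[-1]]
        dropped += bad
        kept = [c for c in kept if c not in bad]
    if dropped:
        warnings.warn(f"screened aliased/degenerate candidates: {dropped}")
    return kept


def ols_fit(
    X: np.ndarray, y: np.ndarray, variables: "list[str] | None" = None
) -> RegressionModel:
    """Ordinary least squares with intercept.

    ``X`` holds the predictor columns (no intercept column); the intercept
    is always included.  Rank-deficient designs raise an error naming the
    offending columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = list(variables) if variables is not None else [f"x{i+1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("variable name count must match design columns")
    design = np.column_stack([np.ones(n), X])
    p = k + 1
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(design) < p:
        bad = _collinear_columns(design, ["intercept"] + names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - p
    resid_var = float(resid @ resid / dof)
    xtx_inv = np.linalg.inv(design.T @ design)
    stderr = np.sqrt(resid_var * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / stderr
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return RegressionModel(
        variables=tuple(names), coef=beta, stderr=stderr, pvalues=pvals,
        r_squared=r2, resid_var=resid_var, n_obs=n,
    )


def select_variables(
    data: pd.DataFrame,
    candidates: "list[str]",
    target: str = EE_TARGET,
    alpha: float = 0.05,
    direction: str = "backward",
) -> list[str]:
    """Stepwise variable selection at significance ``alpha``.

    Backward (default): fit the full model and repeatedly drop the
    largest-p variable with p >= alpha.  Forward: greedily add the variable
    with the smallest p below alpha.  The intercept is always kept; an
    emptied set returns ``[]`` (intercept-only) with a warning.

    Candidates that are zero-variance or exactly linear combinations of
    earlier candidates (aliased — e.g. relative band powers that sum to
    100 by construction) are screened out with a warning before stepwise
    fitting; they carry no selectable information and would make every fit
    rank-deficient.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate variable")
    y = data[target].to_numpy(dtype=float)
    candidates = _screen_aliased(data, list(candidates))

    def _fit(varnames: list[str]) -> RegressionModel:
        return ols_fit(data[varnames].to_numpy(dtype=float), y, varnames)

    if direction == "backward":
        current = list(candidates)
        while current:
            model = _fit(current)
            pv = model.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] >= alpha:
                current.pop(worst)
            else:
                return current
        warnings.warn("backward elimination removed every variable; "
                      "returning intercept-only model")
        return []
    if direction == "forward":
        current: list[str] = []
        remaining = list(candidates)
        while remaining:
            best_name, best_p = None, alpha
            for name in remaining:
                model = _fit(current + [name])
                p = model.pvalues[-1]
                if p < best_p:
                    best_name, best_p = name, p
            if best_name is None:
                break
            current.append(best_name)
            remaining.remove(best_name)
        if not current:
            warnings.warn("forward selection added no variable; "
                          "returning intercept-only model")
        return current
    raise ValueError("direction must be 'backward' or 'forward'")


# -------------------------------------------------------------- model specs

@dataclass(frozen=True)
class EEModelSpec:
    """data_type x model_type cell of the four-model comparison."""

    with_hrv: bool
    activity_specific: bool

    @property
    def name(self) -> str:
        num = {(False, False): "I", (True, False): "II",
               (False, True): "III", (True, True): "IV"}
        return f"Model {num[(self.with_hrv, self.activity_specific)]}"

    @property
    def data_type(self) -> str:
        return "IMU+ECG" if self.with_hrv else "IMU"

    @property
    def model_type(self) -> str:
        return "activity-specific" if self.activity_specific else "single"

    def candidates(self) -> list[str]:
        base = list(ANTHROPOMETRICS) + list(IMU_NAMES)
        return base + (list(HRV_NAMES) if self.with_hrv else [])


MODEL_SPECS: tuple[EEModelSpec, ...] = (
    EEModelSpec(False, False),   # I
    EEModelSpec(True, False),    # II
    EEModelSpec(False, True),    # III
    EEModelSpec(True, True),     # IV
)

_STATIC_SET = {a.value for a in STATIC_ACTIVITIES}


def _category(activity: str) -> str:
    return "static" if activity in _STATIC_SET else "dynamic"


def fit_ee(
    table: pd.DataFrame,
    spec: EEModelSpec,
    fold: Fold,
    alpha: float = 0.05,
) -> dict[str, RegressionModel]:
    """Fit the spec's model(s) on a fold's training subjects.

    Returns ``{"single": model}`` or ``{"static": ..., "dynamic": ...}``;
    each model is variable-selected then refit on its own training minutes.
    """
    train = table[table["subject_id"].isin(fold.train_subjects)]
    cands = spec.candidates()
    if not spec.activity_specific:
        return {"single": _select_and_fit(train, cands, alpha)}
    out = {}
    for cat in ("static", "dynamic"):
        sub = train[train["activity"].map(_category) == cat]
        if sub.empty:
            raise ValueError(f"no {cat} minutes in training data")
        out[cat] = _select_and_fit(sub, cands, alpha)
    return out


def _select_and_fit(
    train: pd.DataFrame, candidates: list[str], alpha: float
) -> RegressionModel:
    chosen = select_variables(train, candidates, alpha=alpha)
    if not chosen:
        y = train[EE_TARGET].to_numpy(dtype=float)
        n = y.size
        mean = float(y.mean())
        var = float(y.var(ddof=1))
        return RegressionModel(
            variables=(), coef=np.array([mean]),
            stderr=np.array([np.sqrt(var / n)]),
            pvalues=np.array([0.0]), r_squared=0.0,
            resid_var=var, n_obs=n,
        )
    return ols_fit(train[chosen].to_numpy(dtype=float),
                   train[EE_TARGET].to_numpy(dtype=float), chosen)


def evaluate_ee(
    models: dict[str, RegressionModel],
    test: pd.DataFrame,
) -> pd.Series:
    """Per-activity RMSE (kcal/min) of fitted model(s) on test minutes.

    Activity-specific models route each minute by its true category."""
    if "single" in models:
        pred = models["single"].predict(test)
    else:
        pred = np.empty(len(test))
        cats = test["activity"].map(_category).to_numpy()
        for cat, model in models.items():
            mask = cats == cat
            if mask.any():
                pred[mask] = model.predict(test[mask])
    err = test[EE_TARGET].to_numpy(dtype=float) - pred
    out = {}
    for act in ACTIVITY_ORDER:
        mask = (test["activity"] == act).to_numpy()
        out[act] = float(np.sqrt(np.mean(err[mask] ** 2))) if mask.any() else np.nan
    return pd.Series(out, name="rmse")


@dataclass
class EEReport:
    """Fold-by-activity RMSEs and fitted-model summaries for one spec."""

    spec: EEModelSpec
    rmse: pd.DataFrame               # index fold test subject, columns activity
    models: list[dict[str, RegressionModel]] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return sum(len(m) for m in self.models)

    def activity_means(self) -> pd.Series:
        return self.rmse.mean(axis=0)

    def overall_mean(self) -> float:
        return float(self.activity_means().mean())

    def to_json(self) -> str:
        return json.dumps({
            "model": self.spec.name,
            "data_type": self.spec.data_type,
            "model_type": self.spec.model_type,
            "rmse_by_activity": {k: round(v, 4)
                                 for k, v in self.activity_means().items()},
            "rmse_overall": round(self.overall_mean(), 4),
            "n_fitted_models": self.n_models,
            "models": [
                {cat: m.coef_dict() for cat, m in fold_models.items()}
                for fold_models in self.models
            ],
        }, indent=2)


def run_ee(
    table: pd.DataFrame,
    spec: EEModelSpec,
    alpha: float = 0.05,
) -> EEReport:
    """Leave-one-subject-out evaluation of one EE model family."""
    subjects = list(dict.fromkeys(table["subject_id"]))
    folds = loso_folds(subjects, validation=False)
    cands = spec.candidates()
    rows, models = {}, []
    for fold in folds:
        # flagged-missing feature values are imputed with training-fold means
        train_means = table.loc[
            table["subject_id"].isin(fold.train_subjects), cands
        ].mean()
        filled = table.copy()
        filled[cands] = filled[cands].fillna(train_means)
        fitted = fit_ee(filled, spec, fold, alpha=alpha)
        test = filled[filled["subject_id"] == fold.test_subject]
        rows[fold.test_subject] = evaluate_ee(fitted, test)
        models.append(fitted)
    rmse = pd.DataFrame(rows).T
    rmse.index.name = "test_subject"
    return EEReport(spec=spec, rmse=rmse, models=models)


# --------------------------------------------------------------------- ANOVA

def anova_2x2(cells: pd.DataFrame) -> dict:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``cells`` is long-format with columns ``data_type``, ``model_type`` and
    ``rmse`` (one row per fold-by-activity observation).  Both factors must
    have two levels with equal cell sizes.  Returns F, df and p for the two
    main effects and the interaction, plus the sums of squares and
    cell/marginal means.
    """
    for col in ("data_type", "model_type", "rmse"):
        if col not in cells.columns:
            raise ValueError(f"cells missing column {col!r}")
    a_levels = sorted(cells["data_type"].unique())
    b_levels = sorted(cells["model_type"].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("anova_2x2 requires exactly two levels per factor")
    sizes = cells.groupby(["data_type", "model_type"]).size()
    if sizes.size != 4 or sizes.nunique() != 1:
        raise ValueError("unbalanced layout: all four cells must have equal size")
    n = int(sizes.iloc[0])
    y = cells["rmse"].to_numpy(dtype=float)
    grand = y.mean()

    cell_means = cells.groupby(["data_type", "model_type"])["rmse"].mean()
    a_means = cells.groupby("data_type")["rmse"].mean()
    b_means = cells.groupby("model_type")["rmse"].mean()

    ss_a = 2 * n * float(((a_means - grand) ** 2).sum())
    ss_b = 2 * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cells
    df_err = 4 * n - 4
    ms_err = ss_err / df_err

    def _effect(ss: float) -> dict:
        f = (ss / 1.0) / ms_err if ms_err > 0 else 0.0
        return {"F": f, "df": (1, df_err), "p": float(stats.f.sf(f, 1, df_err)),
                "ss": ss}

    return {
        "data_type": _effect(ss_a),
        "model_type": _effect(ss_b),
        "interaction": _effect(ss_ab),
        "ss_error": ss_err,
        "ss_total": ss_tot,
        "grand_mean": grand,
        "cell_means": {f"{a}/{b}": v for (a, b), v in cell_means.items()},
        "marginal_means": {
            "data_type": a_means.to_dict(),
            "model_type": b_means.to_dict(),
        },
        "marginal_sd": {
            "data_type": cells.groupby("data_type")["rmse"].std(ddof=1).to_dict(),
            "model_type": cells.groupby("model_type")["rmse"].std(ddof=1).to_dict(),
        },
    }


def rmse_cells(reports: "list[EEReport]") -> pd.DataFrame:
    """Long-format fold-by-activity RMSE observations for anova_2x2."""
    frames = []
    for rep in reports:
        long = rep.rmse.reset_index().melt(
            id_vars="test_subject", var_name="activity", value_name="rmse"
        )
        long["data_type"] = rep.spec.data_type
        long["model_type"] = rep.spec.model_type
        frames.append(long)
    return pd.concat(frames, ignore_index=True).dropna(subset=["rmse"])
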