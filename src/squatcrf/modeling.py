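"""V̇O2peak prediction models and their validation statistics.

Three published linear models predict absolute V̇O2peak (L/min) from subject
characteristics and the motion-decay feature R_FSmax:

* ``model_1a`` — all healthy subjects: weight, age, sex, R_FSmax;
* ``model_1b`` — healthy subjects of normal-to-low fitness
  (V̇O2peak/weight < 40 ml/min/kg): same predictors;
* ``model_2``  — male coronary-artery-disease patients: weight, age, R_FSmax
  (no sex term, the group is single-sex).

Sex is coded female = 0, male = 1, consistent with the positive published sex
coefficients and with males' higher absolute V̇O2peak.

Besides applying the published coefficient sets, this module refits models de
novo (forced-entry OLS and forward stepwise selection), validates them by
leave-one-subject-out cross-validation (RMSE_cv absolute and as a percentage
of the group's mean measured V̇O2peak, r_cv), and computes Bland-Altman
agreement (bias ± 1.96 SD of the held-out prediction−measurement
differences), partial correlations, and fitness-category error breakdowns.

Note the distinction maintained throughout: ``r`` correlates in-sample fitted
values with measurements; ``r_cv`` correlates held-out predictions with
measurements.  Bias and limits of agreement are computed from held-out
predictions — in-sample OLS residuals have mean exactly zero by construction,
so an in-sample bias would be uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ContractError,
    SchemaError,
    SingularDesignError,
    UndefinedResultError,
)

SEX_CODING = {"female": 0.0, "male": 1.0}
PREDICTOR_POOL = ("weight", "age", "sex", "rfsmax")

#: Weight-normalized fitness threshold (ml/min/kg) below which a healthy
#: subject counts as "normal to low" fitness.
NORMAL_TO_LOW_THRESHOLD = 40.0
#: Fitness-category bin edges, ml/min/kg, lower-inclusive.
CATEGORY_EDGES = (20.0, 30.0, 40.0, 50.0)


@dataclass
class SubjectRecord:
    """One subject: characteristics, measured V̇O2peak and extracted R_FSmax.

    ``vo2peak`` is the measured criterion value in L/min (final 30-second
    average of a maximal cycle-ergometer test); it is consumed, never
    computed, by this package.
    """

    subject_id: str
    weight: float  # kg
    height: float  # cm
    age: float  # years
    sex: str  # "female" | "male"
    vo2peak: float  # L/min
    rfsmax: float  # g²·samples
    group: str = "healthy"  # "healthy" | "cad"

    def __post_init__(self) -> None:
        for name in ("weight", "height", "age", "vo2peak"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.sex not in SEX_CODING:
            raise ContractError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.group not in ("healthy", "cad"):
            raise ContractError(f"group must be 'healthy' or 'cad', got {self.group!r}")
        if self.rfsmax < 0:
            raise ContractError(f"rfsmax must be non-negative, got {self.rfsmax!r}")


@dataclass
class ModelSpec:
    """A named predictor set with intercept-first coefficients (L/min units)."""

    name: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one per predictor

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.predictors) + 1:
            raise ContractError(
                f"model {self.name!r}: need {len(self.predictors) + 1} coefficients "
                f"(intercept + predictors), got {len(self.coefficients)}"
            )


#: Published coefficient sets (intercept, then coefficients in predictor order).
PUBLISHED_MODELS: dict[str, ModelSpec] = {
    "model_1a": ModelSpec(
        name="model_1a",
        predictors=("weight", "age", "sex", "rfsmax"),
        coefficients=np.array([1.587, 0.01443, -0.01759, 0.674, 0.01712]),
    ),
    "model_1b": ModelSpec(
        name="model_1b",
        predictors=("weight", "age", "sex", "rfsmax"),
        coefficients=np.array([0.145, 0.0299, -0.0182, 0.18, 0.0305]),
    ),
    "model_2": ModelSpec(
        name="model_2",
        predictors=("weight", "age", "rfsmax"),
        coefficients=np.array([4.624, 0.00311, -0.0516, 0.123]),
    ),
}


@dataclass
class FitResult:
    """In-sample OLS fit: per-coefficient inference and global fit statistics."""

    terms: tuple[str, ...]  # "intercept" + predictors
    params: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r: float  # Pearson corr(fitted, measured)
    adj_r2: float
    rmse: float  # root mean squared residual, L/min
    n: int
    df_resid: int


@dataclass
class CVResult:
    """Leave-one-subject-out validation of a fixed predictor set."""

    predictions: np.ndarray  # held-out prediction per subject, L/min
    measured: np.ndarray
    rmse_cv: float  # L/min
    rmse_cv_pct: float  # % of mean measured V̇O2peak
    r_cv: float
    bias: float  # mean(predicted − measured), L/min
    loa_upper: float
    loa_lower: float

    @property
    def n(self) -> int:
        return len(self.predictions)


@dataclass
class FitnessCategory:
    """Weight-normalized fitness of one subject and its 10 ml/min/kg bin."""

    rel_fitness: float  # ml/min/kg
    label: str  # "20-30" | "30-40" | "40-50"
    normal_to_low: bool  # rel_fitness < 40
    clamped: bool  # outside [20, 50) and assigned to the nearest edge bin


# ---------------------------------------------------------------------------
# Subject-table I/O
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "group", "sex", "weight", "height", "age", "vo2peak", "rfsmax")

#: Column aliases accepted on input (lower-cased, stripped).  Covers the
#: package's own dialect (weight_kg, ...) and bracketed spreadsheet headers.
_COLUMN_ALIASES: dict[str, str] = {
    "subject": "subject_id",
    "id": "subject_id",
    "weight_kg": "weight",
    "weight [kg]": "weight",
    "body weight": "weight",
    "height_cm": "height",
    "height [cm]": "height",
    "age_yr": "age",
    "age_years": "age",
    "age [years]": "age",
    "vo2peak_lmin": "vo2peak",
    "vo2peak [l/min]": "vo2peak",
    "vo2_peak": "vo2peak",
    "rfs_max": "rfsmax",
    "rfsmax [g2 samples]": "rfsmax",
}

_SEX_VALUES = {
    "f": "female", "female": "female", "0": "female", "w": "female",
    "m": "male", "male": "male", "1": "male",
}


def normalize_subject_table(df: pd.DataFrame) -> pd.DataFrame:
    """Map alias column names / sex encodings to the canonical schema."""
    df = df.copy()
    df.columns = [
        _COLUMN_ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns
    ]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table is missing required columns: {missing}")
    df["sex"] = [
        _SEX_VALUES.get(str(v).strip().lower(), str(v).strip().lower()) for v in df["sex"]
    ]
    df["group"] = [str(v).strip().lower() for v in df["group"]]
    for col in ("weight", "height", "age", "vo2peak", "rfsmax"):
        df[col] = pd.to_numeric(df[col])
    return df[list(REQUIRED_COLUMNS)]


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a subject table from CSV or XLSX into the canonical schema."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    return normalize_subject_table(raw)


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def subjects_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects])[list(REQUIRED_COLUMNS)]


# ---------------------------------------------------------------------------
# Prediction and fitting
# ---------------------------------------------------------------------------

def _predictor_value(subject, name: str) -> float:
    if isinstance(subject, SubjectRecord):
        subject = vars(subject)
    elif isinstance(subject, pd.Series):
        subject = subject.to_dict()
    if name not in subject or subject[name] is None or (
        isinstance(subject[name], float) and np.isnan(subject[name])
    ):
        raise ContractError(f"subject is missing required predictor {name!r}")
    value = subject[name]
    if name == "sex":
        if value not in SEX_CODING:
            raise ContractError(f"sex must be 'female' or 'male', got {value!r}")
        return SEX_CODING[value]
    return float(value)


def predict(model: ModelSpec, subject) -> float:
    """Apply a linear model to one subject (SubjectRecord, Series or mapping)."""
    value = float(model.coefficients[0])
    for name, coef in zip(model.predictors, model.coefficients[1:]):
        value += float(coef) * _predictor_value(subject, name)
    return value


def design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    """Intercept-first design matrix with sex coded female=0 / male=1."""
    cols = [np.ones(len(df))]
    for name in predictors:
        if name not in df.columns:
            raise ContractError(f"subject table is missing required predictor {name!r}")
        if name == "sex":
            bad = set(df["sex"]) - set(SEX_CODING)
            if bad:
                raise ContractError(f"unrecognized sex values: {sorted(bad)}")
            cols.append(df["sex"].map(SEX_CODING).to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_ols(
    df: pd.DataFrame, predictors: Sequence[str], *, name: str = "custom"
) -> tuple[ModelSpec, FitResult]:
    """Forced-entry ordinary least squares of V̇O2peak on the given predictors."""
    predictors = tuple(predictors)
    y = df["vo2peak"].to_numpy(dtype=float)
    X = design_matrix(df, predictors)
    n, k = X.shape
    if n < k + 1:
        raise ContractError(f"need n > {k} subjects to fit {len(predictors)} predictors, got n={n}")
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError(
            f"design matrix is rank deficient for predictors {predictors}"
        )
    res = sm.OLS(y, X).fit()
    fitted = res.fittedvalues
    if np.std(fitted) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(fitted, y)[0])
    fit = FitResult(
        terms=("intercept",) + predictors,
        params=np.asarray(res.params),
        se=np.asarray(res.bse),
        t=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        r=r,
        adj_r2=float(res.rsquared_adj),
        rmse=float(np.sqrt(np.mean(res.resid**2))),
        n=n,
        df_resid=int(res.df_resid),
    )
    spec = ModelSpec(name=name, predictors=predictors, coefficients=np.asarray(res.params))
    return spec, fit


def stepwise_forward(
    df: pd.DataFrame,
    candidates: Sequence[str] = PREDICTOR_POOL,
    p_enter: float = 0.05,
) -> ModelSpec:
    """Forward stepwise selection: repeatedly add the candidate with the
    smallest entry p-value while it is below ``p_enter``.

    Ties break on candidate order; selection may stop at the intercept-only
    model.  The published models were fitted forced-entry (retained terms
    have p-values far above conventional entry thresholds), so this operation
    is offered as a separate, configurable selection tool.
    """
    candidates = list(candidates)
    if not candidates:
        raise ContractError("candidate pool must be non-empty")
    selected: list[str] = []
    while True:
        best: tuple[float, str] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            try:
                _, fit = fit_ols(df, selected + [cand])
            except SingularDesignError:
                continue
            p_cand = float(fit.p[-1])
            if best is None or p_cand < best[0]:
                best = (p_cand, cand)
        if best is None or best[0] >= p_enter:
            break
        selected.append(best[1])
    if not selected:
        y = df["vo2peak"].to_numpy(dtype=float)
        return ModelSpec(name="custom", predictors=(), coefficients=np.array([float(np.mean(y))]))
    spec, _ = fit_ols(df, selected)
    return spec


def bland_altman(predicted: np.ndarray, measured: np.ndarray) -> tuple[float, float, float]:
    """Agreement statistics: (bias, loa_upper, loa_lower).

    Differences are predicted − measured; limits of agreement are
    bias ± 1.96·SD of the differences (sample SD, n−1 denominator).
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ContractError(
            f"predicted and measured must be equal-length vectors, got "
            f"{predicted.shape} vs {measured.shape}"
        )
    if len(predicted) < 2:
        raise ContractError("agreement statistics require at least 2 subjects")
    d = predicted - measured
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias + 1.96 * sd, bias - 1.96 * sd


def loocv(df: pd.DataFrame, predictors: Sequence[str]) -> CVResult:
    """Leave-one-subject-out cross-validation of a fixed predictor set.

    Each subject is predicted by a model refitted on the remaining n−1; the
    predictor set itself is held fixed across folds (no per-fold selection).
    """
    predictors = tuple(predictors)
    y = df["vo2peak"].to_numpy(dtype=float)
    X = design_matrix(df, predictors)
    n, k = X.shape
    if n < 3:
        raise ContractError(f"LOOCV requires at least 3 subjects, got n={n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, yi = X[mask], y[mask]
        if np.linalg.matrix_rank(Xi) < k:
            raise SingularDesignError(
                f"design matrix is rank deficient in LOOCV fold {i} "
                f"(subject held out: {df.iloc[i].get('subject_id', i)!r})"
            )
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        preds[i] = X[i] @ beta
    rmse_cv = float(np.sqrt(np.mean((preds - y) ** 2)))
    rmse_cv_pct = 100.0 * rmse_cv / float(np.mean(y))
    r_cv = float(stats.pearsonr(preds, y)[0]) if np.std(preds) > 0 and np.std(y) > 0 else float("nan")
    bias, loa_upper, loa_lower = bland_altman(preds, y)
    return CVResult(
        predictions=preds,
        measured=y,
        rmse_cv=rmse_cv,
        rmse_cv_pct=rmse_cv_pct,
        r_cv=r_cv,
        bias=bias,
        loa_upper=loa_upper,
        loa_lower=loa_lower,
    )


def partial_correlation(
    df: pd.DataFrame,
    predictor: str,
    controls: Sequence[str],
    target: str = "vo2peak",
) -> float:
    """Partial correlation of ``target`` with ``predictor`` given ``controls``.

    Both variables are residualized on the controls (with intercept) by OLS
    and the Pearson correlation of the residuals is returned.  With no
    controls this reduces to the simple Pearson correlation.
    """
    controls = tuple(controls)
    n = len(df)
    if n <= len(controls) + 2:
        raise ContractError(
            f"partial correlation needs n > {len(controls) + 2}, got n={n}"
        )
    Z = design_matrix(df, controls)
    ty = df[target].to_numpy(dtype=float) if target in df.columns else None
    if ty is None:
        raise ContractError(f"target column {target!r} not in table")
    tx = design_matrix(df, (predictor,))[:, 1]

    def _resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
        return v - Z @ beta

    ry, rx = _resid(ty), _resid(tx)
    if np.std(ry) < 1e-12 or np.std(rx) < 1e-12:
        raise UndefinedResultError(
            "partial correlation undefined: residuals are (near-)constant"
        )
    return float(stats.pearsonr(rx, ry)[0])


# ---------------------------------------------------------------------------
# Fitness categories
# ---------------------------------------------------------------------------

def fitness_category(subject=None, *, vo2peak: float | None = None, weight: float | None = None) -> FitnessCategory:
    """Weight-normalized fitness (ml/min/kg) and its 10-unit bin.

    Bins are lower-inclusive: [20,30), [30,40), [40,50).  A value outside
    [20, 50) is assigned to the nearest edge bin with ``clamped=True``.  The
    ``normal_to_low`` flag marks relative fitness below 40 ml/min/kg.
    """
    if subject is not None:
        vo2peak = _predictor_value(subject, "vo2peak")
        weight = _predictor_value(subject, "weight")
    if vo2peak is None or weight is None or weight <= 0 or vo2peak <= 0:
        raise ContractError("fitness_category needs positive vo2peak (L/min) and weight (kg)")
    rel = 1000.0 * vo2peak / weight
    edges = CATEGORY_EDGES
    clamped = not (edges[0] <= rel < edges[-1])
    clipped = min(max(rel, edges[0]), np.nextafter(edges[-1], -np.inf))
    idx = int(np.searchsorted(edges, clipped, side="right")) - 1
    label = f"{edges[idx]:.0f}-{edges[idx + 1]:.0f}"
    return FitnessCategory(
        rel_fitness=rel,
        label=label,
        normal_to_low=rel < NORMAL_TO_LOW_THRESHOLD,
        clamped=clamped,
    )


def rmse_by_category(cv: CVResult, df: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Held-out RMSE per fitness-category bin.

    Returns a mapping bin label → {n, rmse_cv, rmse_cv_pct} where the percent
    denominator is that bin's mean measured V̇O2peak.  Empty bins are absent
    from the mapping.
    """
    if cv.n != len(df):
        raise ContractError(
            f"CV result covers {cv.n} subjects but the table has {len(df)}"
        )
    labels = [
        fitness_category(vo2peak=v, weight=w).label
        for v, w in zip(df["vo2peak"], df["weight"])
    ]
    out: dict[str, dict[str, float]] = {}
    for label in sorted(set(labels)):
        mask = np.array([lab == label for lab in labels])
        errs = cv.predictions[mask] - cv.measured[mask]
        rmse = float(np.sqrt(np.mean(errs**2)))
        out[label] = {
            "n": int(mask.sum()),
            "rmse_cv": rmse,
            "rmse_cv_pct": 100.0 * rmse / float(np.mean(cv.measured[mask])),
        }
    return out
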