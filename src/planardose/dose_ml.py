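"""Tabular machine-learning prediction of organ absorbed doses.

Each record couples planar-imaging-derived features (anterior/posterior ROI
count rates, oblique-view body thickness, organ S-value, effective
attenuation coefficient) with patient demographics (age, BMI) and the organ
label; the target is the organ absorbed dose in Gy. Four regressor families
are supported: a small multilayer perceptron, support-vector regression
with a radial-basis kernel, a depth-limited decision tree, and linear
regression.

Pipeline order mirrors standard tabular practice: clean (drop rows with a
missing target, impute missing features, remove |z| > z_max outliers),
split 75/25 with a fixed seed, fit normalization constants on the training
split only (min-max for the two imaging count features, z-score for the
rest), transform both splits with the saved constants, train, evaluate with
MAE / MSE / RMSE overall and per organ.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FEATURES",
    "IMAGING_FEATURES",
    "CohortTable",
    "ModelSpec",
    "TrainedModel",
    "MetricReport",
    "ComparisonResult",
    "preprocess",
    "split",
    "fit_normalization",
    "transform",
    "train",
    "predict",
    "evaluate",
    "percent_error",
    "paired_comparison",
    "save_model",
    "load_model",
]

#: Numeric feature columns, in canonical order.
FEATURES = (
    "I_A_cps",
    "I_B_cps",
    "thickness_cm",
    "s_value",
    "mu_e_cm1",
    "bmi_kg_m2",
    "age_y",
)
#: Imaging-derived features get min-max scaling; the rest are z-scored.
IMAGING_FEATURES = ("I_A_cps", "I_B_cps")
TARGET = "target_dose_Gy"
ORGAN_COL = "organ"


@dataclass
class CohortTable:
    """A cohort of per-patient, per-organ records plus preprocessing state."""

    records: pd.DataFrame
    normalization_params: dict = field(default_factory=dict)
    split_seed: int | None = None
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.records, pd.DataFrame):
            self.records = pd.DataFrame(self.records)
        missing = [c for c in FEATURES + (ORGAN_COL,) if c not in self.records.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def schema_hash(self) -> str:
        cols = ",".join(self.records.columns)
        return hashlib.sha256(cols.encode()).hexdigest()[:16]


_FAMILIES = ("mlp", "svr", "tree", "linreg")

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    # 3 hidden layers of 6 neurons, adam at lr 1e-3, batch 50, L2 penalty,
    # early stopping on a held-out fraction of the training data.
    "mlp": {
        "hidden_layer_sizes": (6, 6, 6),
        "activation": "relu",
        "solver": "adam",
        "learning_rate_init": 1e-3,
        "batch_size": 50,
        "alpha": 1e-3,
        "early_stopping": True,
        "n_iter_no_change": 200,
        "max_iter": 6000,
    },
    "svr": {"kernel": "rbf", "C": 100.0, "gamma": 10.0},
    # min leaf size 5; 20 internal splits -> at most 21 leaves
    "tree": {"min_samples_leaf": 5, "max_leaf_nodes": 21},
    "linreg": {"solver": "closed_form", "max_iter": 1000},
}


@dataclass
class ModelSpec:
    """A regressor family with its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {_FAMILIES}")
        allowed = set(_DEFAULT_HYPERPARAMS[self.family])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ValueError(
                f"unrecognized hyperparameters for {self.family}: {sorted(unknown)}"
            )
        merged = dict(_DEFAULT_HYPERPARAMS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


@dataclass
class TrainedModel:
    family: str
    estimator: object
    feature_columns: list[str]
    organ_categories: list[str]
    normalization_params: dict
    seed: int
    schema_hash: str
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class MetricReport:
    """MAE, MSE and RMSE, overall and per organ."""

    mse: float
    mae: float
    rmse: float
    per_organ: dict[str, dict[str, float]]
    n: int

    def __post_init__(self) -> None:
        if abs(self.rmse ** 2 - self.mse) > 1e-12 * max(self.mse, 1.0):
            raise ValueError("rmse**2 must equal mse")
        if min(self.mse, self.mae, self.rmse) < 0:
            raise ValueError("metrics must be >= 0")


@dataclass
class ComparisonResult:
    test_name: str
    p_value: float
    mean_percent_error: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(cohort: CohortTable, config: dict | None = None) -> CohortTable:
    """Clean a cohort: drop rows with a missing target, impute missing
    features, remove z-score outliers.

    config keys: ``z_max`` (default 3.0), ``impute`` ("mean" or
    "interpolate"; interpolation runs along patient_id-then-organ order).
    Normalization is a separate, split-aware step (`fit_normalization` /
    `transform`).
    """
    cfg = {"z_max": 3.0, "impute": "mean"}
    cfg.update(config or {})
    df = cohort.records.copy()
    if df.empty:
        raise ValueError("empty cohort")

    if TARGET in df.columns:
        df = df.dropna(subset=[TARGET])

    feat = [c for c in FEATURES if c in df.columns]
    if cfg["impute"] == "interpolate":
        order = [c for c in ("patient_id", ORGAN_COL) if c in df.columns]
        if order:
            df = df.sort_values(order, kind="stable")
        df[feat] = df[feat].interpolate(limit_direction="both")
        df[feat] = df[feat].fillna(df[feat].mean())
    else:
        df[feat] = df[feat].fillna(df[feat].mean())

    z_max = float(cfg["z_max"])
    keep = pd.Series(True, index=df.index)
    for col in feat:
        sd = df[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        keep &= ((df[col] - df[col].mean()) / sd).abs() <= z_max
    df = df[keep].reset_index(drop=True)

    return CohortTable(
        records=df,
        normalization_params=dict(cohort.normalization_params),
        split_seed=cohort.split_seed,
        metadata=dict(cohort.metadata),
    )


def split(cohort: CohortTable, seed: int) -> tuple[CohortTable, CohortTable]:
    """Deterministic 75/25 train/test split."""
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 records to split 75/25")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_train = int(round(0.75 * n))
    df = cohort.records
    make = lambda rows: CohortTable(
        records=df.iloc[rows].reset_index(drop=True),
        normalization_params=dict(cohort.normalization_params),
        split_seed=seed,
        metadata=dict(cohort.metadata),
    )
    return make(idx[:n_train]), make(idx[n_train:])


def fit_normalization(train_table: CohortTable) -> dict:
    """Normalization constants from the training split only.

    Imaging count features: min-max to [0, 1]; all other numeric features:
    z-score with the training mean and sample SD. Constant features are
    passed through with a warning.
    """
    df = train_table.records
    params: dict[str, dict] = {}
    for col in FEATURES:
        x = df[col].to_numpy(dtype=float)
        if col in IMAGING_FEATURES:
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi - lo <= 1e-12 * max(abs(hi), 1.0):
                warnings.warn(f"feature {col} is constant; passed through", stacklevel=2)
                params[col] = {"kind": "identity"}
            else:
                params[col] = {"kind": "minmax", "min": lo, "max": hi}
        else:
            mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if np.isnan(sd) or sd <= 1e-12 * max(abs(mu), 1.0):
                warnings.warn(f"feature {col} is constant; passed through", stacklevel=2)
                params[col] = {"kind": "identity"}
            else:
                params[col] = {"kind": "zscore", "mean": mu, "sd": sd}
    return params


def transform(table: CohortTable, params: dict) -> CohortTable:
    """Apply saved normalization constants. Idempotent: a table already
    normalized with the same constants is returned unchanged, so test-split
    transforms can never re-fit or double-apply."""
    if table.normalized and table.normalization_params == params:
        return table
    df = table.records.copy()
    for col, p in params.items():
        if p["kind"] == "minmax":
            df[col] = (df[col] - p["min"]) / (p["max"] - p["min"])
        elif p["kind"] == "zscore":
            df[col] = (df[col] - p["mean"]) / p["sd"]
    return CohortTable(
        records=df,
        normalization_params=dict(params),
        split_seed=table.split_seed,
        normalized=True,
        metadata=dict(table.metadata),
    )


# ---------------------------------------------------------------------------
# Training / prediction


def _design_matrix(
    table: CohortTable, organ_categories: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric features plus one-hot organ indicators (single pooled model)."""
    df = table.records
    if organ_categories is None:
        organ_categories = sorted(df[ORGAN_COL].astype(str).unique())
    cols = list(FEATURES)
    X = df[cols].to_numpy(dtype=float)
    onehot = np.column_stack(
        [(df[ORGAN_COL].astype(str) == org).to_numpy(float) for org in organ_categories]
    )
    X = np.hstack([X, onehot])
    names = cols + [f"organ={o}" for o in organ_categories]
    return X, names, organ_categories


def train(spec: ModelSpec, train_table: CohortTable) -> TrainedModel:
    """Fit one pooled regressor on the (already normalized) training split."""
    df = train_table.records
    if TARGET not in df.columns or df[TARGET].isna().any():
        raise ValueError("training table must have a complete target column")
    X, names, organs = _design_matrix(train_table)
    if np.isnan(X).any():
        bad = sorted(set(np.argwhere(np.isnan(X))[:, 0].tolist()))
        raise ValueError(f"NaN features in rows {bad}")
    y = df[TARGET].to_numpy(dtype=float)

    hp = dict(spec.hyperparameters)
    if spec.family == "mlp":
        hp["batch_size"] = min(hp["batch_size"], max(len(y) // 2, 1))
        est = MLPRegressor(random_state=spec.seed, **hp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            est.fit(X, y)
    elif spec.family == "svr":
        est = SVR(**hp)
        est.fit(X, y)
    elif spec.family == "tree":
        est = DecisionTreeRegressor(random_state=spec.seed, **hp)
        est.fit(X, y)
    else:  # linreg
        solver = hp.get("solver", "closed_form")
        if solver == "closed_form":
            est = _OLSLinear()
            est.fit(X, y)
        elif solver == "lbfgs":
            est = _LBFGSLinear(max_iter=int(hp.get("max_iter", 1000)))
            est.fit(X, y)
        else:
            raise ValueError(f"unknown linreg solver {solver!r}")

    return TrainedModel(
        family=spec.family,
        estimator=est,
        feature_columns=names,
        organ_categories=organs,
        normalization_params=dict(train_table.normalization_params),
        seed=spec.seed,
        schema_hash=train_table.schema_hash,
        hyperparameters=hp,
    )


class _OLSLinear:
    """Ordinary least squares via the minimum-norm LAPACK solution.

    Unlike scikit-learn's LinearRegression, no small-singular-value cutoff
    is applied, so coefficients on badly scaled designs (counts in the
    hundreds next to S-values around 1e-5) are recovered exactly."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OLSLinear":
        Xb = np.hstack([X, np.ones((len(y), 1))])
        w, *_ = np.linalg.lstsq(Xb, y, rcond=None)
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_


class _LBFGSLinear:
    """Least-squares linear model solved by L-BFGS-B (iteration-capped),
    matching the closed-form solution on well-posed problems."""

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LBFGSLinear":
        from scipy.optimize import minimize

        # column preconditioning: quasi-Newton steps stall on designs whose
        # feature scales span many orders of magnitude
        scale = np.maximum(np.abs(X).max(axis=0), 1e-300)
        Xb = np.hstack([X / scale, np.ones((len(y), 1))])

        def loss(w):
            r = Xb @ w - y
            return 0.5 * float(r @ r), Xb.T @ r

        w0 = np.zeros(Xb.shape[1])
        sol = minimize(loss, w0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "gtol": 1e-12,
                                "ftol": 1e-15})
        self.coef_ = sol.x[:-1] / scale
        self.intercept_ = float(sol.x[-1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_


def predict(model: TrainedModel, table: CohortTable) -> np.ndarray:
    """Predict doses; the table is normalized with the model's saved
    constants if it is not already."""
    table = transform(table, model.normalization_params)
    X, _, _ = _design_matrix(table, model.organ_categories)
    return np.asarray(model.estimator.predict(X), dtype=float)


def evaluate(model: TrainedModel, test_table: CohortTable) -> MetricReport:
    """MAE / MSE / RMSE of the model on a test split, overall and per organ."""
    if len(test_table) == 0:
        raise ValueError("empty test table")
    y = test_table.records[TARGET].to_numpy(dtype=float)
    yhat = predict(model, test_table)
    return metric_report(y, yhat, test_table.records[ORGAN_COL].astype(str))


def metric_report(y, yhat, organs=None) -> MetricReport:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    err = y - yhat
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    per_organ: dict[str, dict[str, float]] = {}
    if organs is not None:
        organs = np.asarray(organs)
        for org in sorted(set(organs.tolist())):
            sel = organs == org
            e = err[sel]
            per_organ[org] = {
                "mse": float(np.mean(e ** 2)),
                "mae": float(np.mean(np.abs(e))),
                "rmse": float(np.sqrt(np.mean(e ** 2))),
            }
    return MetricReport(
        mse=mse, mae=mae, rmse=float(np.sqrt(mse)), per_organ=per_organ, n=len(y)
    )


def percent_error(pred_dose: float, ref_dose: float) -> float:
    """Signed percent error (pred - ref) / ref * 100."""
    if ref_dose == 0:
        raise ZeroDivisionError("percent error undefined for zero reference dose")
    return (pred_dose - ref_dose) / ref_dose * 100.0


def paired_comparison(doses_a, doses_b, alpha: float = 0.05) -> ComparisonResult:
    """Compare two paired dose sets.

    Shapiro-Wilk normality of the paired differences decides the test:
    normal -> paired t-test, otherwise Wilcoxon signed-rank. Returns which
    test ran, its p-value, and the mean signed percent error of a vs b.
    """
    a = np.asarray(doses_a, dtype=float)
    b = np.asarray(doses_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired comparison needs equal-length vectors of >= 3")
    diff = a - b
    mpe = float(np.mean((a - b) / b * 100.0)) if np.all(b != 0) else float("nan")
    if np.all(diff == 0):
        return ComparisonResult("degenerate", 1.0, 0.0, degenerate=True)
    sw_p = float(stats.shapiro(diff).pvalue)
    if sw_p >= alpha:
        res = stats.ttest_rel(a, b)
        return ComparisonResult("paired_t", float(res.pvalue), mpe)
    res = stats.wilcoxon(a, b)
    return ComparisonResult("wilcoxon", float(res.pvalue), mpe)


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "family": model.family,
            "estimator": model.estimator,
            "feature_columns": model.feature_columns,
            "organ_categories": model.organ_categories,
            "normalization_params": model.normalization_params,
            "seed": model.seed,
            "schema_hash": model.schema_hash,
            "hyperparameters": model.hyperparameters,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(**payload)
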