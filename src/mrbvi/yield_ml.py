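"""Leave-one-out yield prediction from multi-date vegetation-index features.

Each plot is one sample; its feature vector concatenates the per-plot mean
of every vegetation index on every date of the prediction window
(index-major, date-minor), and the response is the plot's harvest yield in
grams per hundred grains.  Four regressors are supported:

``BP``
    A single-hidden-layer backpropagation network (10 logistic units,
    L-BFGS training with an iteration cap, L2 penalty 1.0 — a sane amount
    of shrinkage for ~20 samples against ~64 features).
``SVM``
    Epsilon-SVR with an RBF kernel (C=10, ε=0.1, γ=1/n_features).
``RF``
    A 500-tree random forest.
``ELM``
    An extreme learning machine implemented here: hidden-layer input
    weights and biases drawn once, uniformly from [−1, 1], and the
    hidden-to-output weights solved in closed form as a ridge-regularized
    least-squares problem (no iterative training).

Evaluation is leave-one-out: each plot is predicted by a model trained on
the remaining plots, with all preprocessing (per-column mean imputation and
z-scoring for the scale-sensitive learners) fitted on the training fold
only.  BP and ELM are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .evaluation import EvalResult, metrics
from .indices import ALL_INDICES, IndexId

__all__ = [
    "FeatureMatrix",
    "YieldModelSpec",
    "ElmRegressor",
    "MODEL_KINDS",
    "build_features",
    "make_model",
    "fit_elm",
    "loo_predict",
    "LooResult",
    "error_band_report",
]

MODEL_KINDS = ("BP", "SVM", "RF", "ELM")


@dataclass
class FeatureMatrix:
    """Plot-by-(index, date) design matrix aligned with the yield response."""

    X: np.ndarray  # (n_plots, n_indices * n_dates)
    y: np.ndarray  # (n_plots,)
    plot_ids: list[str]
    column_labels: list[tuple[str, str]]  # (index id, date label), index-major

    @property
    def n_plots(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class YieldModelSpec:
    """Which regressor to run, with its hyperparameters and RNG seed.

    ``standardize=None`` resolves to the kind's convention: z-scored
    features for BP/SVM/ELM, raw features for the scale-free RF.
    """

    kind: str = "SVM"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    standardize: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"model kind must be one of {MODEL_KINDS}; got {self.kind!r}")

    @property
    def standardize_resolved(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.kind != "RF"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ElmRegressor(BaseEstimator, RegressorMixin):
    """Extreme learning machine: random hidden layer, closed-form readout.

    ``fit`` draws the input weights ``W_in`` (hidden × features) and biases
    ``b`` uniformly from [−1, 1] using ``random_state``, computes hidden
    activations ``H = sigmoid(X W_inᵀ + b)``, and solves the ridge problem
    ``min ‖H β − y‖² + α‖β‖²`` for the output weights via an SVD (exact and
    stable even at α → 0, where the fit interpolates whenever ``H`` has
    full row rank).
    """

    def __init__(
        self, hidden_size: int = 20, alpha: float = 1e-2, random_state: int = 0
    ):
        self.hidden_size = hidden_size
        self.alpha = alpha
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.W_in_.T + self.b_)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a 2-d matrix without undefined entries")
        if np.all(X.std(axis=0) == 0):
            raise ValueError("degenerate X: every column is constant")
        rng = np.random.default_rng(self.random_state)
        self.W_in_ = rng.uniform(-1.0, 1.0, size=(self.hidden_size, X.shape[1]))
        self.b_ = rng.uniform(-1.0, 1.0, size=self.hidden_size)
        H = self._hidden(X)
        # ridge solution via SVD: beta = V diag(s / (s^2 + alpha)) U^T y
        U, s, Vt = np.linalg.svd(H, full_matrices=False)
        self.beta_ = Vt.T @ ((s / (s**2 + self.alpha)) * (U.T @ y))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self._hidden(X) @ self.beta_


def fit_elm(
    X: np.ndarray, y: np.ndarray, spec: YieldModelSpec | None = None
) -> ElmRegressor:
    """Fit an ELM from a model spec (convenience wrapper around the class)."""
    spec = spec or YieldModelSpec(kind="ELM")
    if spec.kind != "ELM":
        raise ValueError(f"fit_elm requires an ELM spec, got {spec.kind!r}")
    hyper = dict(spec.hyperparameters)
    model = ElmRegressor(
        hidden_size=int(hyper.get("hidden_size", 20)),
        alpha=float(hyper.get("alpha", 1e-2)),
        random_state=spec.seed,
    )
    return model.fit(X, y)


def make_model(spec: YieldModelSpec):
    """Instantiate the (unfitted) regressor for a spec."""
    h = dict(spec.hyperparameters)
    if spec.kind == "BP":
        return MLPRegressor(
            hidden_layer_sizes=(int(h.get("hidden_size", 10)),),
            activation="logistic",
            solver="lbfgs",
            alpha=float(h.get("alpha", 1.0)),
            max_iter=int(h.get("max_iter", 500)),
            random_state=spec.seed,
        )
    if spec.kind == "SVM":
        return SVR(
            kernel="rbf",
            C=float(h.get("C", 10.0)),
            epsilon=float(h.get("epsilon", 0.1)),
            gamma=h.get("gamma", "auto"),  # 1 / n_features
        )
    if spec.kind == "RF":
        return RandomForestRegressor(
            n_estimators=int(h.get("n_estimators", 500)),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.kind == "ELM":
        return ElmRegressor(
            hidden_size=int(h.get("hidden_size", 20)),
            alpha=float(h.get("alpha", 1e-2)),
            random_state=spec.seed,
        )
    raise ValueError(f"unknown model kind {spec.kind!r}")


def build_features(
    observations: pd.DataFrame,
    yields: Mapping[str, float] | pd.DataFrame,
    window: Sequence[str],
    indices: Iterable[IndexId] = ALL_INDICES,
) -> FeatureMatrix:
    """Assemble the plot × (index, date) matrix for a date window.

    Rows are sorted by plot id and columns ordered index-major, date-minor
    (all dates of the first index, then the second, ...), so feature layout
    is deterministic regardless of input row order.  A plot without a yield
    raises; cells with no green pixels remain NaN and are imputed fold-wise
    during cross-validation.
    """
    if isinstance(yields, pd.DataFrame):
        yields = dict(zip(yields["plot_id"], yields["yield"]))
    indices = [IndexId(i) for i in indices]
    window = sorted(window)
    available = set(observations["date"])
    missing_dates = [d for d in window if d not in available]
    if missing_dates:
        raise ValueError(f"window dates absent from observations: {missing_dates}")
    plot_ids = sorted(observations["plot_id"].unique())
    for pid in plot_ids:
        if pid not in yields:
            raise ValueError(f"plot {pid!r} has no yield record")
    sub = observations[observations["date"].isin(window)]
    wide = sub.pivot_table(
        index="plot_id",
        columns="date",
        values=[i.value for i in indices],
        aggfunc="first",
        dropna=False,
    ).reindex(plot_ids)
    column_labels = [(i.value, d) for i in indices for d in window]
    X = np.column_stack([wide[(idx, d)].to_numpy() for idx, d in column_labels])
    y = np.array([yields[p] for p in plot_ids], dtype=np.float64)
    return FeatureMatrix(X=X, y=y, plot_ids=plot_ids, column_labels=column_labels)


class FoldPreprocessor:
    """Per-fold preprocessing: column-mean imputation, optional z-scoring.

    Statistics come from the training rows only, so held-out plots can
    never leak into the standardization.
    """

    def __init__(self, standardize: bool):
        self.standardize = standardize

    def fit(self, X: np.ndarray) -> "FoldPreprocessor":
        X = np.asarray(X, dtype=np.float64)
        self.col_mean_ = np.nanmean(X, axis=0)
        self.col_mean_ = np.where(np.isfinite(self.col_mean_), self.col_mean_, 0.0)
        Xf = self.transform_impute_only(X)
        self.center_ = Xf.mean(axis=0) if self.standardize else np.zeros(X.shape[1])
        sd = Xf.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0) if self.standardize else np.ones(X.shape[1])
        return self

    def transform_impute_only(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64).copy()
        nan = ~np.isfinite(X)
        X[nan] = np.broadcast_to(self.col_mean_, X.shape)[nan]
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (self.transform_impute_only(X) - self.center_) / self.scale_


@dataclass
class LooResult:
    """Leave-one-out predictions and their error summary."""

    predictions: pd.Series  # indexed by plot_id
    truths: pd.Series
    result: EvalResult
    spec: YieldModelSpec


def loo_predict(features: FeatureMatrix, spec: YieldModelSpec) -> LooResult:
    """Leave-one-out prediction of every plot's yield under one model spec.

    For each of the n plots the model is trained on the other n−1 (folds are
    the identity ordering of sorted plot ids, identical across model kinds),
    then RMSE/MAE are computed over the n held-out predictions.
    """
    n = features.n_plots
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 plots")
    preds = np.empty(n)
    base = make_model(spec)
    for i in range(n):
        train = np.arange(n) != i
        prep = FoldPreprocessor(spec.standardize_resolved).fit(features.X[train])
        Xtr = prep.transform(features.X[train])
        Xte = prep.transform(features.X[[i]])
        try:
            model = clone(base).fit(Xtr, features.y[train])
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"{spec.kind} fit failed on fold {features.plot_ids[i]!r}: {exc}"
            ) from exc
        preds[i] = float(np.asarray(model.predict(Xte)).ravel()[0])
    predictions = pd.Series(preds, index=features.plot_ids, name="prediction")
    truths = pd.Series(features.y, index=features.plot_ids, name="yield")
    result = metrics(preds, features.y, with_ae=not np.any(features.y == 0))
    return LooResult(predictions=predictions, truths=truths, result=result, spec=spec)


def error_band_report(
    predictions: Sequence[float], truths: Sequence[float], band: float = 0.15
) -> int:
    """Count plots whose relative prediction error exceeds the band.

    The 15% default mirrors the error lines conventionally drawn on
    predicted-vs-actual yield scatterplots.
    """
    P = np.asarray(predictions, dtype=np.float64)
    M = np.asarray(truths, dtype=np.float64)
    if P.shape != M.shape:
        raise ValueError("predictions and truths must have equal length")
    if np.any(M == 0):
        raise ZeroDivisionError("relative error undefined: some truth is 0")
    return int(np.sum(np.abs(P - M) / np.abs(M) > band))
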