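"""PLS concentration regression with leave-one-concentration-out
validation, per-concentration coefficient of variation, and the limit
of quantification (LoQ).

PLS projects spectra X and target y into latent variables maximizing
their covariance (NIPALS-style sequential deflation, via scikit-learn);
with as many components as the rank of X on noiseless linear data it
reproduces ordinary least squares. Validation holds out *all*
replicates of one concentration at a time, so every spectrum is
blind-predicted by a model that never saw its level. The LoQ is the
smallest tested concentration c* such that every tested concentration
>= c* keeps CV below the threshold (2 % by default): a single failing
lowest level moves the LoQ up one grid step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .synthetic import ConcentrationDataset

__all__ = [
    "PLSModel",
    "RegressionReport",
    "pls_fit",
    "pls_predict",
    "locoo_validate",
    "coefficient_of_variation",
    "limit_of_quantification",
    "r_squared",
]


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (L, n_components) x-weights
    x_loadings: np.ndarray   # (L, n_components)
    y_loadings: np.ndarray   # (n_components,)
    beta: np.ndarray         # (L,) regression coefficients on centered X
    intercept: float

    @property
    def n_features(self) -> int:
        return self.beta.size


def pls_fit(X, y, n_components: int = 2) -> PLSModel:
    """Fit a PLS regression of concentration on spectra (rows = spectra)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_spectra, n_wavenumbers)")
    if y.shape != (X.shape[0],):
        raise ValueError("y must have one value per spectrum")
    if np.var(y) == 0:
        raise ValueError("target has zero variance")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {X.shape[0]} samples "
            f"x {X.shape[1]} wavenumbers"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    beta = pls.coef_.reshape(-1)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=pls.x_weights_.copy(),
        x_loadings=pls.x_loadings_.copy(),
        y_loadings=pls.y_loadings_.reshape(-1).copy(),
        beta=beta,
        intercept=y_mean - float(x_mean @ beta),
    )


def pls_predict(model: PLSModel, X) -> np.ndarray:
    """Predict concentrations: ``(X - x_mean) @ beta + y_mean``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} wavenumbers; model was trained on "
            f"{model.n_features}"
        )
    return X @ model.beta + model.intercept


@dataclass
class RegressionReport:
    concentrations: np.ndarray   # tested levels, ascending
    y_true: np.ndarray           # per held-out spectrum
    y_pred: np.ndarray
    r2: float
    cv_percent: dict             # level -> CV in percent
    loq: float | None
    sparsity_level: float = 0.0
    seed: int = 0

    @property
    def max_cv_percent(self) -> float:
        return max(self.cv_percent.values())


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SSE/SST (can be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need >= 2 points")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("y_true has zero variance")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - sse / sst


def coefficient_of_variation(predictions) -> float:
    """100 * sample standard deviation / mean of one level's predictions."""
    p = np.asarray(predictions, dtype=float)
    if p.size < 2:
        raise ValueError("need >= 2 predictions for a CV")
    mean = p.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean prediction")
    return 100.0 * p.std(ddof=1) / mean


def limit_of_quantification(report: RegressionReport,
                            cv_threshold: float = 2.0) -> float | None:
    """Smallest tested concentration c* with CV < threshold at every
    tested concentration >= c*; ``None`` if even the largest fails."""
    levels = np.sort(np.asarray(list(report.cv_percent), dtype=float))
    if levels.size == 0:
        raise ValueError("report has no per-concentration CVs")
    loq = None
    for level in levels[::-1]:  # walk down while the tail keeps passing
        if report.cv_percent[level] < cv_threshold:
            loq = float(level)
        else:
            break
    return loq


def locoo_validate(
    dataset: ConcentrationDataset,
    n_components: int = 2,
    sparsity_level: float = 0.0,
    seed: int = 0,
    cv_threshold: float = 2.0,
) -> RegressionReport:
    """Leave-one-concentration-out validation.

    For each level c, train on all spectra with concentration != c and
    predict all spectra at c; every spectrum is predicted exactly once.
    """
    levels = np.unique(dataset.concentrations)
    if levels.size < 3:
        raise ValueError("leave-one-concentration-out needs >= 3 distinct levels")
    y_true = []
    y_pred = []
    cv_percent: dict = {}
    for level in levels:
        held = dataset.y == level
        if not held.any():
            raise ValueError(f"concentration {level} has zero replicates")
        model = pls_fit(dataset.spectra[~held], dataset.y[~held], n_components)
        preds = pls_predict(model, dataset.spectra[held])
        y_true.append(dataset.y[held])
        y_pred.append(preds)
        cv_percent[float(level)] = coefficient_of_variation(preds)
    y_true = np.concatenate(y_true)
    y_pred = np.concatenate(y_pred)
    report = RegressionReport(
        concentrations=levels,
        y_true=y_true,
        y_pred=y_pred,
        r2=r_squared(y_true, y_pred),
        cv_percent=cv_percent,
        loq=None,
        sparsity_level=sparsity_level,
        seed=seed,
    )
    report.loq = limit_of_quantification(report, cv_threshold)
    return report
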