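"""Epsilon-insensitive support vector regression over the six descriptors.

Kernel menu: linear, quadratic (polynomial of degree 2), RBF, and sigmoid.
Descriptors are z-score standardized on training statistics inside the
engine — SVR is scale-sensitive, and raw-unit fitting would silently let
PPB (percent scale) dominate. Models are evaluated with MSE, MAE and R²
on training and held-out sets, and kernels are compared on a small
hyperparameter grid ranked by test MSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .data import Dataset, MODELING_DESCRIPTORS, as_xy

KERNELS = ("linear", "quadratic", "rbf", "sigmoid")
_SKLEARN_KERNEL = {"linear": "linear", "quadratic": "poly",
                   "rbf": "rbf", "sigmoid": "sigmoid"}


class SvrError(ValueError):
    pass


@dataclass
class RegressionMetrics:
    mse: float
    mae: float
    r2: float | None  # None (flagged) when n < 2
    n: int

    def to_dict(self) -> dict:
        return {"MSE": self.mse, "MAE": self.mae, "R2": self.r2, "n": self.n}


@dataclass
class SvrModel:
    kernel: str
    C: float
    epsilon: float
    estimator: SVR
    names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray

    @property
    def support_indices(self) -> np.ndarray:
        """Training-record indices of the support vectors."""
        return self.estimator.support_

    @property
    def dual_coef(self) -> np.ndarray:
        return self.estimator.dual_coef_[0]

    def predict(self, data) -> np.ndarray:
        if isinstance(data, Dataset):
            X = data.descriptor_matrix(self.names)
        else:
            X = np.asarray(data, dtype=float)
        return self.estimator.predict((X - self.x_mean) / self.x_sd)


def fit_svr(data, kernel: str = "linear", C: float = 1.0,
            epsilon: float = 0.1, seed: int | None = None,
            names=MODELING_DESCRIPTORS, split: str | None = None) -> SvrModel:
    """Fit epsilon-SVR on z-scored descriptors. Deterministic given inputs.

    ``seed`` is accepted for interface symmetry; the underlying solver is
    deterministic, so it has no effect.
    """
    if kernel not in KERNELS:
        raise SvrError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    if C <= 0 or epsilon < 0:
        raise SvrError("require C > 0 and epsilon >= 0")
    X, y = as_xy(data, names=names, split=split)
    if len(y) == 0:
        raise SvrError("training set is empty")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    extra = {"degree": 2, "coef0": 1.0} if kernel == "quadratic" else {}
    est = SVR(kernel=_SKLEARN_KERNEL[kernel], C=C, epsilon=epsilon,
              gamma="scale", **extra)
    est.fit((X - x_mean) / x_sd, y)
    return SvrModel(kernel=kernel, C=C, epsilon=epsilon, estimator=est,
                    names=tuple(names), x_mean=x_mean, x_sd=x_sd)


def evaluate_svr(model: SvrModel, data, split: str | None = None
                 ) -> RegressionMetrics:
    """MSE, MAE and R² (about the evaluated set's own mean)."""
    X, y = as_xy(data, names=model.names, split=split)
    if len(y) == 0:
        raise SvrError("evaluation set is empty")
    yhat = model.predict(X)
    err = y - yhat
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    if len(y) < 2 or np.allclose(y, y.mean()):
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / float(np.sum((y - y.mean()) ** 2))
    return RegressionMetrics(mse=mse, mae=mae, r2=r2, n=len(y))


def metrics_table(model: SvrModel, train_data, test_data) -> pd.DataFrame:
    """Training/validation metrics table (rows MSE, R², MAE)."""
    tr = evaluate_svr(model, train_data)
    te = evaluate_svr(model, test_data)
    return pd.DataFrame(
        {"Training Set": [tr.mse, tr.r2, tr.mae],
         "Validation Set": [te.mse, te.r2, te.mae]},
        index=["MSE", "R2", "MAE"],
    )


def kernel_selection(data, kernels=KERNELS, C_grid=(0.1, 1.0, 10.0),
                     epsilon_grid=(0.01, 0.1, 0.3), seed: int | None = None,
                     names=MODELING_DESCRIPTORS) -> pd.DataFrame:
    """Compare kernels: best grid point per kernel by test-set MSE.

    ``data`` must carry train/test split labels (Dataset) or be a pair of
    ((X_train, y_train), (X_test, y_test)). Returns a table ranked by test
    MSE; ties break by kernel list order (stable sort).
    """
    if len(kernels) < 1:
        raise SvrError("need at least one kernel")
    if isinstance(data, Dataset):
        train, test = data.subset("train"), data.subset("test")
        train_xy = (train.descriptor_matrix(names), train.response())
        test_xy = (test.descriptor_matrix(names), test.response())
    else:
        train_xy, test_xy = data

    rows = []
    for kern in kernels:
        best = None
        for C in C_grid:
            for eps in epsilon_grid:
                m = fit_svr(train_xy, kernel=kern, C=C, epsilon=eps, names=names)
                te = evaluate_svr(m, test_xy)
                if best is None or te.mse < best["test_MSE"]:
                    tr = evaluate_svr(m, train_xy)
                    best = {"kernel": kern, "C": C, "epsilon": eps,
                            "train_MSE": tr.mse, "train_MAE": tr.mae,
                            "train_R2": tr.r2, "test_MSE": te.mse,
                            "test_MAE": te.mae, "test_R2": te.r2}
        rows.append(best)
    table = pd.DataFrame(rows)
    table = table.sort_values("test_MSE", kind="stable").reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table
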