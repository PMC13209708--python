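"""Best-subset multiple linear regression with QSAR validation metrics.

The core model of the package is a six-descriptor MLR for BChE pIC50:

    pIC50 = 1.68 + 0.481 nRot − 5.14 Flex − 1.75 Fsp3
                 + 1.18 logD − 0.847 caco2 − 0.0591 PPB

(the published equation; frozen here as :data:`PUBLISHED_MODEL` and applied
to raw, unstandardized descriptors). New models are fit by exhaustive
best-subset search over 2..6 descriptors, screened for collinearity at
tolerance 0.1, validated with R², adjusted R², leave-one-out Q²
(1 − PRESS/TSS), the model F statistic, and RMSE of prediction on a held-out
test set.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CompoundRecord, Dataset, MODELING_DESCRIPTORS, as_xy
from .screening import correlation_matrix, tolerances_from_correlation, screen_subset


class FitError(ValueError):
    pass


@dataclass
class FitStats:
    """Training-fit and validation statistics of a linear model."""

    n: int
    k: int
    r2: float
    r2_adj: float
    f_stat: float
    p_value: float
    q2_loo: float | None = None
    rmse_pred: float | None = None

    @staticmethod
    def adjusted_r2(r2: float, n: int, k: int) -> float:
        return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)

    @staticmethod
    def f_statistic(r2: float, n: int, k: int) -> float:
        return (r2 / k) / ((1.0 - r2) / (n - k - 1))


@dataclass
class LinearModel:
    """Intercept + per-descriptor slopes with standard errors."""

    names: tuple[str, ...]
    intercept: float
    intercept_se: float
    coef: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    stats: FitStats | None = None

    def __post_init__(self) -> None:
        if any(se < 0 for _, se in self.coef.values()) or self.intercept_se < 0:
            raise ValueError("standard errors must be nonnegative")

    def predict_one(self, record: CompoundRecord | dict) -> float:
        desc = record.descriptors if isinstance(record, CompoundRecord) else record
        missing = [n for n in self.names if n not in desc]
        if missing:
            rid = getattr(record, "id", "?")
            raise FitError(f"record {rid!r} missing descriptor(s) {missing}")
        return self.intercept + sum(self.coef[n][0] * desc[n] for n in self.names)

    def predict(self, data) -> np.ndarray:
        if isinstance(data, Dataset):
            return np.array([self.predict_one(r) for r in data.records])
        X = np.asarray(data, dtype=float)
        b = np.array([self.coef[n][0] for n in self.names])
        return self.intercept + X @ b

    def to_json(self) -> str:
        doc = {
            "format": "sunqsar-linear-model",
            "version": 1,
            "names": list(self.names),
            "intercept": [self.intercept, self.intercept_se],
            "coefficients": {n: list(v) for n, v in self.coef.items()},
        }
        if self.stats is not None:
            doc["stats"] = {k: v for k, v in vars(self.stats).items()}
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        doc = json.loads(text)
        if doc.get("format") != "sunqsar-linear-model":
            raise ValueError("not a sunqsar linear-model document")
        stats = FitStats(**doc["stats"]) if "stats" in doc else None
        return cls(
            names=tuple(doc["names"]),
            intercept=doc["intercept"][0],
            intercept_se=doc["intercept"][1],
            coef={n: tuple(v) for n, v in doc["coefficients"].items()},
            stats=stats,
        )


#: The frozen published six-descriptor equation (coefficients ± SE as printed).
PUBLISHED_MODEL = LinearModel(
    names=MODELING_DESCRIPTORS,
    intercept=1.68, intercept_se=1.26,
    coef={
        "nRot": (0.481, 0.053),
        "Flex": (-5.14, 0.77),
        "Fsp3": (-1.75, 0.47),
        "logD": (1.18, 0.14),
        "caco2": (-0.847, 0.195),
        "PPB": (-0.0591, 0.0113),
    },
    stats=FitStats(n=100, k=6, r2=0.706,
                   r2_adj=FitStats.adjusted_r2(0.706, 100, 6),
                   f_stat=FitStats.f_statistic(0.706, 100, 6),
                   p_value=float(sps.f.sf(FitStats.f_statistic(0.706, 100, 6), 6, 93)),
                   q2_loo=0.667, rmse_pred=0.59),
)


def predict_published(data) -> np.ndarray | float:
    """Apply the frozen published equation to a record, dict, or Dataset."""
    if isinstance(data, (CompoundRecord, dict)):
        return PUBLISHED_MODEL.predict_one(data)
    return PUBLISHED_MODEL.predict(data)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(data, subset=MODELING_DESCRIPTORS, split: str | None = None) -> LinearModel:
    """Ordinary least squares of pIC50 on the given descriptor subset.

    Classical standard errors from the unbiased residual variance;
    rank-deficient designs are rejected naming the collinear columns.
    """
    subset = tuple(subset)
    X, y = as_xy(data, names=subset, split=split)
    n, k = X.shape
    if n <= k + 1:
        raise FitError(f"need n > k+1 ({k + 1}), have n={n}")
    D = _design(X)
    rank = np.linalg.matrix_rank(D)
    if rank < k + 1:
        collinear = _collinear_columns(D, subset)
        raise FitError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    sigma2 = rss / (n - k - 1)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    f = FitStats.f_statistic(r2, n, k) if r2 < 1 else np.inf
    stats = FitStats(
        n=n, k=k, r2=r2,
        r2_adj=FitStats.adjusted_r2(r2, n, k),
        f_stat=f,
        p_value=float(sps.f.sf(f, k, n - k - 1)),
    )
    return LinearModel(
        names=subset,
        intercept=float(beta[0]), intercept_se=float(se[0]),
        coef={nm: (float(beta[i + 1]), float(se[i + 1]))
              for i, nm in enumerate(subset)},
        stats=stats,
    )


def _collinear_columns(D: np.ndarray, names) -> list[str]:
    """Name columns involved in an exact linear dependency (via QR)."""
    _, R = np.linalg.qr(D)
    small = np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    return [(["<intercept>"] + list(names))[i] for i in np.flatnonzero(small)]


def q2_loo(data, subset=MODELING_DESCRIPTORS, split: str | None = None) -> float:
    """Leave-one-out cross-validated Q² = 1 − PRESS/TSS.

    PRESS via the hat-matrix shortcut (e_i / (1 − h_ii)); TSS about the
    training mean. Identical to refitting n times with one point left out.
    """
    subset = tuple(subset)
    X, y = as_xy(data, names=subset, split=split)
    n, k = X.shape
    if n <= k + 2:
        raise FitError(f"LOO needs n > k+2 ({k + 2}), have n={n}")
    D = _design(X)
    if np.linalg.matrix_rank(D) < k + 1:
        raise FitError("rank-deficient design")
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    h = np.diag(H)
    if np.any(h > 1 - 1e-10):
        raise FitError("a leave-one-out fold is rank-deficient (leverage 1)")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def evaluate_test(model: LinearModel, data, split: str | None = "test") -> float:
    """RMSE of prediction on a held-out set; stores it on model.stats."""
    if isinstance(data, Dataset):
        ds = data.subset(split) if split else data
        if len(ds) == 0:
            raise FitError("test set is empty")
        yhat = model.predict(ds)
        y = ds.response()
    else:
        X, y = as_xy(data, names=model.names)
        if len(y) == 0:
            raise FitError("test set is empty")
        yhat = model.predict(X)
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if model.stats is not None:
        model.stats.rmse_pred = rmse
    return rmse


@dataclass
class SubsetSearchResult:
    """Admissible subsets ranked by the selection criterion (best first)."""

    criterion: str
    ranked: list[tuple[tuple[str, ...], float]]  # (subset, criterion value)
    models: list[tuple[tuple[str, ...], LinearModel]] = field(default_factory=list)

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.ranked[0][0]

    @property
    def best_model(self) -> LinearModel:
        return self.models[0][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subset": ["+".join(s) for s, _ in self.ranked],
             "size": [len(s) for s, _ in self.ranked],
             self.criterion: [v for _, v in self.ranked]}
        )


def best_subset_search(data, pool=MODELING_DESCRIPTORS, kmin: int = 2,
                       kmax: int = 6, tolerance_threshold: float = 0.1,
                       criterion: str = "r2_adj", split: str | None = None,
                       fit_models: int = 10) -> SubsetSearchResult:
    """Exhaustive best-subset OLS over subsets of size kmin..kmax.

    Subsets failing the collinearity tolerance screen are discarded; the
    rest are ranked by the criterion (default adjusted R²). Ranking uses
    correlation-matrix algebra (exact for complete-case data); full
    LinearModels are fit for the top ``fit_models`` subsets.
    """
    pool = tuple(pool)
    if criterion not in ("r2_adj", "r2", "q2_loo"):
        raise ValueError(f"unknown criterion {criterion!r}")
    X, y = as_xy(data, names=pool, split=split)
    n = len(y)
    # correlation of pool descriptors and response, complete-case
    Z = np.column_stack([X, y])
    R = np.corrcoef(Z, rowvar=False)
    Rxx, rxy = R[:-1, :-1], R[:-1, -1]

    scored: list[tuple[tuple[str, ...], float]] = []
    for k in range(kmin, min(kmax, len(pool)) + 1):
        for combo in itertools.combinations(range(len(pool)), k):
            idx = list(combo)
            sub_R = Rxx[np.ix_(idx, idx)]
            if np.min(tolerances_from_correlation(sub_R)) < tolerance_threshold:
                continue
            try:
                r2 = float(rxy[idx] @ np.linalg.solve(sub_R, rxy[idx]))
            except np.linalg.LinAlgError:
                continue
            r2 = min(1.0, max(0.0, r2))
            subset = tuple(pool[i] for i in idx)
            if criterion == "r2":
                val = r2
            elif criterion == "r2_adj":
                val = FitStats.adjusted_r2(r2, n, k)
            else:
                val = q2_loo((X[:, idx], y), subset=subset)
            scored.append((subset, val))
    if not scored:
        raise FitError("no admissible subset passed the tolerance screen")
    scored.sort(key=lambda t: -t[1])
    models = [(s, fit_ols((X[:, [pool.index(nm) for nm in s]], y), subset=s))
              for s, _ in scored[:fit_models]]
    return SubsetSearchResult(criterion=criterion, ranked=scored, models=models)


DEFAULT_MEAN_SETS = {
    "mean1": ("MLR", "ANN1", "SVR"),
    "mean2": ("MLR", "ANN1", "ANN2", "ANN3", "ANN4", "ANN5", "SVR"),
}


def aggregate_means(predictions: dict[str, float],
                    sets: dict[str, tuple[str, ...]] | None = None
                    ) -> dict[str, float]:
    """Arithmetic means of per-model predictions (full precision).

    ``sets`` maps a mean name to the member model names; a missing member
    prediction is an error.
    """
    sets = sets or DEFAULT_MEAN_SETS
    out = {}
    for mean_name, members in sets.items():
        missing = [m for m in members if m not in predictions]
        if missing:
            raise FitError(f"{mean_name}: missing model prediction(s) {missing}")
        out[mean_name] = float(np.mean([predictions[m] for m in members]))
    return out


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal display rounding (0.005 -> 0.01), used for table output."""
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
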