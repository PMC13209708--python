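"""Descriptor correlation analysis and multicollinearity tolerance screening.

Before a descriptor subset is admitted into a regression model it must pass a
collinearity screen: the *tolerance* of each member — 1 minus the R² of that
descriptor regressed (OLS, with intercept) on the other members — must stay
above a threshold. The default threshold is 0.1; a stricter advisory level of
0.25 is also flagged in reports. For a two-descriptor subset the tolerance
reduces to 1 − r², the pairwise rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, MODELING_DESCRIPTORS

#: Advisory tolerance level; descriptors below it are flagged but not rejected.
STRICT_TOLERANCE = 0.25


class ScreeningError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    names: tuple[str, ...]
    r: np.ndarray  # symmetric, unit diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.names), columns=list(self.names))

    def __getitem__(self, pair):
        a, b = pair
        return self.r[self.names.index(a), self.names.index(b)]


@dataclass
class ToleranceReport:
    tolerances: dict[str, float]
    threshold: float
    admissible: dict[str, bool]
    strict_flags: dict[str, bool]  # True when tolerance < STRICT_TOLERANCE

    @property
    def passes(self) -> bool:
        return all(self.admissible.values())

    def to_frame(self) -> pd.DataFrame:
        names = list(self.tolerances)
        return pd.DataFrame({
            "descriptor": names,
            "tolerance": [self.tolerances[n] for n in names],
            "admissible": [self.admissible[n] for n in names],
            "below_strict_0.25": [self.strict_flags[n] for n in names],
        })


def _columns(data, names):
    """Extract named columns as a DataFrame (NaN where missing).

    ``data`` may be a Dataset, a DataFrame with named columns, or a bare
    array whose columns are taken to be ``names`` in order.
    """
    if isinstance(data, Dataset):
        rows = {n: [r.descriptors.get(n, np.nan) for r in data.records]
                for n in names}
        if "pIC50" in names:
            rows["pIC50"] = [r.pic50 if r.pic50 is not None else np.nan
                             for r in data.records]
        return pd.DataFrame(rows)
    if isinstance(data, pd.DataFrame):
        missing = [n for n in names if n not in data.columns]
        if missing:
            raise ScreeningError(f"column(s) not in table: {missing}")
        return data[list(names)].astype(float)
    arr = np.asarray(data, dtype=float)
    if arr.shape[1] != len(names):
        raise ScreeningError(
            f"array has {arr.shape[1]} columns but {len(names)} names given; "
            "pass a DataFrame to select columns by name"
        )
    return pd.DataFrame(arr, columns=list(names))


def correlation_matrix(data, names=MODELING_DESCRIPTORS) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between the named descriptors.

    ``data`` may be a Dataset or an (n, k) array. A name of ``pIC50`` pulls
    the observed response column. Zero-variance columns are rejected.
    """
    names = tuple(names)
    df = _columns(data, names)
    if len(df.dropna()) < 3:
        raise ScreeningError("need at least 3 complete records")
    stds = df.std(ddof=1)
    flat = [n for n in names if not np.isfinite(stds[n]) or stds[n] == 0]
    if flat:
        raise ScreeningError(f"zero-variance column(s): {flat}")
    r = df.corr(method="pearson").to_numpy()  # pairwise-complete by pandas
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(names, r)


def tolerance(data, target: str, others) -> float:
    """Collinearity tolerance of ``target`` against ``others``: 1 − R²(OLS).

    Computed on records complete for all involved descriptors. A target that
    lies in the span of the others (e.g. a duplicated column) gives 0.
    """
    others = list(others)
    if not others:
        return 1.0
    df = _columns(data, [target] + others).dropna()
    n = len(df)
    if n <= len(others) + 1:
        raise ScreeningError(
            f"need more than {len(others) + 1} complete records, have {n}"
        )
    y = df[target].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ScreeningError(f"zero-variance target {target!r}")
    X = np.column_stack([np.ones(n)] + [df[o].to_numpy(dtype=float) for o in others])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss
    return float(min(1.0, max(0.0, 1.0 - r2)))


def screen_subset(data, subset, threshold: float = 0.1) -> ToleranceReport:
    """Tolerance of every subset member against the rest, with pass flags."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    subset = list(subset)
    tolerances, admissible, strict = {}, {}, {}
    for name in subset:
        rest = [s for s in subset if s != name]
        t = tolerance(data, name, rest)
        tolerances[name] = t
        admissible[name] = t >= threshold
        strict[name] = t < STRICT_TOLERANCE
    return ToleranceReport(tolerances, threshold, admissible, strict)


def tolerances_from_correlation(r_sub: np.ndarray) -> np.ndarray:
    """Per-variable tolerances from a subset correlation matrix.

    For complete-case standardized data, the tolerance of variable i against
    the rest equals 1 / (R⁻¹)ᵢᵢ. Singular matrices (duplicated columns)
    yield tolerance 0 for every variable involved in the dependency.
    """
    k = r_sub.shape[0]
    if k == 1:
        return np.ones(1)
    try:
        inv = np.linalg.inv(r_sub)
    except np.linalg.LinAlgError:
        return np.zeros(k)
    diag = np.diag(inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        tol = np.where(diag > 0, 1.0 / diag, 0.0)
    return np.clip(tol, 0.0, 1.0)
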