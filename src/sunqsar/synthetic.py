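"""Synthetic reference-inhibitor datasets.

The reference set behind the published models — 121 literature BChE
inhibitors with experimental IC50 values — is external and not shipped.
This generator emulates its *statistical* structure so every model stage is
testable: descriptors are drawn from a Gaussian copula with the published
descriptor correlation matrix (n = 121), transformed to drug-like marginal
means/SDs, truncated to physically valid ranges, and pIC50 is computed from
the frozen published linear equation plus Gaussian noise whose default SD
(0.59) is the published prediction RMSE — the best available error-scale
estimate.

The defaults are the study conditions, not knobs: n = 121, sigma = 0.59,
the published correlation block, and marginals chosen to bracket the bulk
of the sunscreen query fixture with mild (≲3%) truncation tails so the
correlation structure survives truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CompoundRecord, Dataset, MODELING_DESCRIPTORS, from_pic50
from .mlr import PUBLISHED_MODEL


class SyntheticError(ValueError):
    pass


#: Published descriptor correlation block, canonical order
#: (nRot, Flex, Fsp3, logD, caco2, PPB).
REFERENCE_CORRELATIONS = np.array([
    # nRot   Flex    Fsp3    logD    caco2   PPB
    [1.000,  0.864,  0.463,  0.274, -0.047,  0.119],   # nRot
    [0.864,  1.000,  0.537,  0.203,  0.056,  0.022],   # Flex
    [0.463,  0.537,  1.000, -0.084,  0.220, -0.393],   # Fsp3
    [0.274,  0.203, -0.084,  1.000, -0.003,  0.648],   # logD
    [-0.047, 0.056,  0.220, -0.003,  1.000, -0.081],   # caco2
    [0.119,  0.022, -0.393,  0.648, -0.081,  1.000],   # PPB
])

#: Drug-like marginal means/SDs for the latent (pre-truncation) descriptors.
#: SDs are anchored on the dispersions implied by the published coefficient
#: standard errors (SE_j = sigma / (sd_j * sqrt(tol_j * n))) and inflated
#: ~1.6x so the reference cloud brackets the wider-ranging sunscreen queries
#: while truncation tails stay small (<~7%).
DEFAULT_MEANS = {"nRot": 7.5, "Flex": 0.60, "Fsp3": 0.45,
                 "logD": 3.5, "caco2": -4.9, "PPB": 78.0}
DEFAULT_SDS = {"nRot": 3.8, "Flex": 0.27, "Fsp3": 0.30,
               "logD": 1.0, "caco2": 0.55, "PPB": 13.5}


@dataclass
class SyntheticConfig:
    n: int = 121
    correlation: np.ndarray = field(
        default_factory=lambda: REFERENCE_CORRELATIONS.copy())
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    sigma: float = 0.59   # pIC50 noise SD
    seed: int = 0
    truncate: bool = True

    def __post_init__(self) -> None:
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (6, 6) or not np.allclose(C, C.T, atol=1e-12):
            raise SyntheticError("correlation must be a symmetric 6x6 matrix")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise SyntheticError("correlation matrix needs a unit diagonal")
        if self.sigma < 0:
            raise SyntheticError("sigma must be >= 0")
        if self.n < 1:
            raise SyntheticError("n must be >= 1")


def nearest_psd(matrix: np.ndarray, eig_tol: float = 1e-12) -> np.ndarray:
    """Frobenius-style PSD repair: clip negative eigenvalues, restore the
    unit diagonal. Idempotent on PSD inputs (returned unchanged)."""
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise SyntheticError("nearest_psd expects a symmetric matrix")
    w, v = np.linalg.eigh(M)
    if w.min() >= -eig_tol:
        return M
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    d = np.where(d > 0, d, 1.0)
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def _truncate(name: str, values: np.ndarray) -> np.ndarray:
    if name == "nRot":
        return np.maximum(np.round(values), 0.0)
    if name == "Flex":
        return np.maximum(values, 0.0)
    if name == "Fsp3":
        return np.clip(values, 0.0, 1.0)
    if name == "PPB":
        return np.clip(values, 0.0, 100.0)
    return values


def generate(cfg: SyntheticConfig | None = None, smiles_library=None) -> Dataset:
    """Draw a synthetic reference Dataset; seeded and reproducible.

    Truncation (integer nonnegative nRot, Flex ≥ 0, Fsp3 ∈ [0, 1],
    PPB ∈ [0, 100]) is applied *before* computing pIC50, so at sigma = 0 the
    generating equation is exactly recoverable by OLS. ``smiles_library``
    (a list of (name, smiles) or a DataFrame with name/smiles columns)
    optionally attaches SMILES cyclically for fingerprint stages.
    """
    cfg = cfg or SyntheticConfig()
    R = nearest_psd(cfg.correlation)
    if np.max(np.abs(R - cfg.correlation)) > 0.05:
        raise SyntheticError(
            "correlation matrix is not PSD-repairable within tolerance "
            "(entry change > 0.05)"
        )
    w, v = np.linalg.eigh(R)
    A = v * np.sqrt(np.clip(w, 0.0, None))  # factor: A @ A.T = R

    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n, 6)) @ A.T
    cols = {}
    for j, name in enumerate(MODELING_DESCRIPTORS):
        x = cfg.means[name] + cfg.sds[name] * Z[:, j]
        cols[name] = _truncate(name, x) if cfg.truncate else x

    X = np.column_stack([cols[n] for n in MODELING_DESCRIPTORS])
    pic50 = PUBLISHED_MODEL.predict(X)
    if cfg.sigma > 0:
        pic50 = pic50 + rng.normal(0.0, cfg.sigma, size=cfg.n)

    smiles_cycle = None
    if smiles_library is not None:
        try:  # DataFrame-like
            smiles_cycle = list(smiles_library["smiles"])
        except (TypeError, KeyError, IndexError):
            smiles_cycle = [s for _, s in smiles_library]

    records = []
    for i in range(cfg.n):
        records.append(CompoundRecord(
            id=f"ref-{i + 1:03d}",
            descriptors={n: float(cols[n][i]) for n in MODELING_DESCRIPTORS},
            smiles=(smiles_cycle[i % len(smiles_cycle)] if smiles_cycle else None),
            pic50=float(pic50[i]),
            ic50_nM=from_pic50(float(pic50[i])),
        ))
    return Dataset(records, seed=cfg.seed)
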