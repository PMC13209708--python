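"""PCA-based applicability domain (AD) in descriptor space.

A QSAR prediction is only trustworthy for query compounds that resemble the
reference (training) chemistry. Here the reference descriptors are z-score
standardized, projected onto the first two principal components of their
correlation matrix, and the domain is the ellipse in (PC1, PC2) score space
that covers a target fraction (default 99%) of the reference compounds.

The ellipse shares the orientation/shape of the 2D score covariance; its
radius is calibrated on the reference scores themselves (the smallest
Mahalanobis radius containing ceil(coverage·n) reference points), which
guarantees at-least-coverage on the reference set and converges to the
chi-square(2) quantile radius for Gaussian scores. Query compounds get an
in/out verdict and a radial distance (1.0 = on the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import Dataset, MODELING_DESCRIPTORS


class AdError(ValueError):
    pass


@dataclass
class ADModel:
    names: tuple[str, ...]
    mean: np.ndarray          # reference descriptor means
    sd: np.ndarray            # reference descriptor SDs
    loadings: np.ndarray      # (d, 2), orthonormal columns, sign-fixed
    explained_variance: np.ndarray  # fractions for all d components
    center: np.ndarray        # (2,) score-space center
    score_cov: np.ndarray     # (2, 2)
    radius2: float            # squared Mahalanobis radius of the ellipse
    chi2_radius2: float       # asymptotic (chi-square) radius, for reference
    coverage: float

    @property
    def ellipse(self) -> dict:
        """Center, semi-axes, and orientation angle (radians) of the ellipse."""
        w, v = np.linalg.eigh(self.score_cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        return {
            "center": self.center.copy(),
            "semi_axes": np.sqrt(w * self.radius2),
            "angle": float(np.arctan2(v[1, 0], v[0, 0])),
        }

    def scores(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.sd
        return Z @ self.loadings

    def distance2(self, scores: np.ndarray) -> np.ndarray:
        d = scores - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.score_cov), d)


@dataclass
class ADVerdict:
    id: str
    pc1: float
    pc2: float
    inside: bool
    distance: float  # radial coordinate; 1.0 = ellipse boundary
    error: str | None = None


def fit_ad(reference, descriptors=MODELING_DESCRIPTORS,
           coverage: float = 0.99) -> ADModel:
    """Fit the applicability-domain ellipse on a reference Dataset/array."""
    if not 0 < coverage < 1:
        raise AdError(f"coverage must be in (0, 1), got {coverage}")
    names = tuple(descriptors)
    if isinstance(reference, Dataset):
        X = reference.descriptor_matrix(names)
    else:
        X = np.asarray(reference, dtype=float)
    n, d = X.shape
    if n < 10:
        raise AdError(f"need at least 10 reference compounds, have {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flat = [names[i] for i in np.flatnonzero(sd == 0)] if names else []
    if np.any(sd == 0):
        raise AdError(f"zero-variance descriptor(s): {flat or 'present'}")
    Z = (X - mean) / sd
    corr = (Z.T @ Z) / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    loadings = v[:, :2].copy()
    # sign convention: largest-magnitude loading positive, for reproducibility
    for j in range(2):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    explained = np.clip(w, 0, None) / d

    scores = Z @ loadings
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    dev = scores - center
    d2 = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(cov), dev)
    k = int(np.ceil(coverage * n))
    radius2 = float(np.sort(d2)[k - 1])
    return ADModel(
        names=names, mean=mean, sd=sd, loadings=loadings,
        explained_variance=explained, center=center, score_cov=cov,
        radius2=radius2, chi2_radius2=float(sps.chi2.ppf(coverage, df=2)),
        coverage=coverage,
    )


def classify(model: ADModel, query) -> list[ADVerdict]:
    """In/out-of-domain verdicts for query compounds.

    A record missing one of the model's descriptors gets a per-record error
    verdict rather than aborting the batch.
    """
    verdicts: list[ADVerdict] = []
    if isinstance(query, Dataset):
        items = [(r.id, r.descriptors) for r in query.records]
    else:
        items = [(f"q{i}", dict(zip(model.names, row)))
                 for i, row in enumerate(np.asarray(query, dtype=float))]
    for cid, desc in items:
        missing = [n for n in model.names if n not in desc]
        if missing:
            verdicts.append(ADVerdict(cid, np.nan, np.nan, False,
                                      np.nan, error=f"missing {missing}"))
            continue
        x = np.array([[desc[n] for n in model.names]], dtype=float)
        s = model.scores(x)
        d2 = float(model.distance2(s)[0])
        dist = float(np.sqrt(d2 / model.radius2))
        verdicts.append(ADVerdict(cid, float(s[0, 0]), float(s[0, 1]),
                                  inside=dist <= 1.0, distance=dist))
    return verdicts


def verdicts_frame(verdicts: list[ADVerdict]) -> pd.DataFrame:
    return pd.DataFrame([vars(v) for v in verdicts])


def plot_ad(model: ADModel, reference=None, verdicts=None, path=None):
    """Scatter of PC1/PC2 with the domain ellipse (optional file export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(6, 5))
    if reference is not None:
        X = (reference.descriptor_matrix(model.names)
             if isinstance(reference, Dataset) else np.asarray(reference, float))
        s = model.scores(X)
        ax.scatter(s[:, 0], s[:, 1], s=12, alpha=0.5, label="reference")
    if verdicts:
        xs = [v.pc1 for v in verdicts if v.error is None]
        ys = [v.pc2 for v in verdicts if v.error is None]
        ax.scatter(xs, ys, s=30, marker="^", color="crimson", label="query")
        for v in verdicts:
            if v.error is None and not v.inside:
                ax.annotate(v.id, (v.pc1, v.pc2), fontsize=8)
    e = model.ellipse
    ax.add_patch(Ellipse(e["center"], 2 * e["semi_axes"][0],
                         2 * e["semi_axes"][1],
                         angle=np.degrees(e["angle"]),
                         fill=False, color="k", ls="--"))
    ax.set_xlabel(f"PC1 ({model.explained_variance[0]:.0%})")
    ax.set_ylabel(f"PC2 ({model.explained_variance[1]:.0%})")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
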