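"""Single-hidden-layer MLP regression trained by BFGS, with input-importance
scoring by global sensitivity analysis (GSA).

The network is y = g(W2 · f(W1 x + b1) + b2) with f, g drawn from
{identity, logistic, tanh, exponential}. Inputs (and the response) are
min-max scaled to [0, 1] internally; the loss is the sum of squares (SOS)
of residuals, minimized by quasi-Newton (BFGS) iterations from a seeded
uniform(−0.5, 0.5) initialization, so training is deterministic per seed.

Architecture selection mimics an automated network search: sample hidden
size and activation pairs at random, train each candidate, and retain the
best few by validation-set SOS.

GSA scores an input as SOS(model with that input frozen at its training
mean) / SOS(full model): a score of 1 or below marks a dispensable input.
The reduced "model without the variable" is mean-substitution without
retraining (a retraining variant is available via ``retrain=True`` but is
not the default convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import MODELING_DESCRIPTORS, as_xy

_ACT = {
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
    "logistic": (lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
                 lambda z, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a ** 2),
    "exponential": (lambda z: np.exp(np.clip(z, -500, 50)),
                    lambda z, a: a),
}

ACTIVATIONS = tuple(_ACT)


class AnnError(ValueError):
    pass


@dataclass
class NetworkModel:
    input_names: tuple[str, ...]
    hidden: int
    act_hidden: str
    act_out: str
    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    sos_train: float = np.nan
    sos_validation: float | None = None
    converged: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.act_hidden not in _ACT or self.act_out not in _ACT:
            raise AnnError(f"activations must be one of {ACTIVATIONS}")
        h, d = self.W1.shape
        if h != self.hidden or self.W2.shape != (1, h):
            raise AnnError("weight shapes inconsistent with layer sizes")

    # --- forward pass ---------------------------------------------------
    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / self.x_range

    def _forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        f = _ACT[self.act_hidden][0]
        g = _ACT[self.act_out][0]
        A = f(Xs @ self.W1.T + self.b1)
        return g(A @ self.W2.T + self.b2)[:, 0]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ys = self._forward_scaled(self._scale_x(X))
        return self.y_min + self.y_range * ys

    def sos(self, X, y) -> float:
        """Sum-of-squares error in original response units."""
        return float(np.sum((self.predict(X) - np.asarray(y, float)) ** 2))


def _unpack(theta, d, h):
    i = 0
    W1 = theta[i:i + h * d].reshape(h, d); i += h * d
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + h].reshape(1, h); i += h
    b2 = theta[i:i + 1]
    return W1, b1, W2, b2


def _loss_grad(theta, Xs, ys, d, h, act_h, act_o):
    fh, dfh = _ACT[act_h]
    fo, dfo = _ACT[act_o]
    W1, b1, W2, b2 = _unpack(theta, d, h)
    Z1 = Xs @ W1.T + b1
    A1 = fh(Z1)
    Z2 = A1 @ W2.T + b2
    out = fo(Z2)[:, 0]
    r = out - ys
    loss = float(r @ r)
    # backprop
    dZ2 = (2.0 * r)[:, None] * dfo(Z2, fo(Z2))
    gW2 = dZ2.T @ A1
    gb2 = dZ2.sum(axis=0)
    dA1 = dZ2 @ W2
    dZ1 = dA1 * dfh(Z1, A1)
    gW1 = dZ1.T @ Xs
    gb1 = dZ1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


def train_mlp(data, hidden: int = 5, activations=("tanh", "identity"),
              seed: int = 0, maxiter: int = 200, gtol: float = 1e-6,
              names=MODELING_DESCRIPTORS, split: str | None = None
              ) -> NetworkModel:
    """Train one MLP by BFGS on SOS loss; deterministic per seed.

    On non-convergence within ``maxiter`` iterations the best iterate is
    returned with ``converged=False``.
    """
    if hidden < 1:
        raise AnnError("hidden layer needs at least one unit")
    act_h, act_o = activations
    if act_h not in _ACT or act_o not in _ACT:
        raise AnnError(f"activations must be one of {ACTIVATIONS}")
    X, y = as_xy(data, names=names, split=split)
    n, d = X.shape
    if n == 0:
        raise AnnError("training set is empty")

    x_min = X.min(axis=0)
    ptp = np.ptp(X, axis=0)
    x_range = np.where(ptp > 0, ptp, 1.0)
    y_min = float(y.min())
    y_range = float(np.ptp(y)) or 1.0
    Xs = (X - x_min) / x_range
    ys = (y - y_min) / y_range

    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=hidden * d + hidden + hidden + 1)
    res = minimize(_loss_grad, theta0, args=(Xs, ys, d, hidden, act_h, act_o),
                   jac=True, method="BFGS",
                   options={"maxiter": maxiter, "gtol": gtol})
    W1, b1, W2, b2 = _unpack(res.x, d, hidden)
    model = NetworkModel(
        input_names=tuple(names), hidden=hidden,
        act_hidden=act_h, act_out=act_o,
        W1=W1, b1=b1, W2=W2, b2=b2,
        x_min=x_min, x_range=x_range, y_min=y_min, y_range=y_range,
        converged=bool(res.success), seed=seed,
    )
    model.sos_train = model.sos(X, y)
    return model


def automated_search(data, n_train_networks: int = 40, n_retain: int = 5,
                     seed: int = 0, hidden_range: tuple[int, int] = (3, 13),
                     maxiter: int = 200, names=MODELING_DESCRIPTORS
                     ) -> list[NetworkModel]:
    """Random architecture search: train many nets, retain the best few.

    Hidden size is sampled uniformly from ``hidden_range`` (inclusive) and
    each activation from the four allowed; candidates are trained on the
    ``train`` split and ranked by nondecreasing SOS on the ``validation``
    split (training SOS if no validation records exist). Reproducible per
    seed. The conventional large-scale search is 500 trained / 50 retained;
    the default here is a desk-scale 40 / 5.
    """
    if n_retain > n_train_networks:
        raise AnnError("cannot retain more networks than are trained")
    from .data import Dataset
    if isinstance(data, Dataset):
        train = data.subset("train")
        if len(train) == 0:
            train = data
        val = data.subset("validation")
        X_tr, y_tr = train.descriptor_matrix(names), train.response()
        X_val, y_val = ((val.descriptor_matrix(names), val.response())
                        if len(val) else (X_tr, y_tr))
    else:
        X_tr, y_tr = as_xy(data, names=names)
        X_val, y_val = X_tr, y_tr

    rng = np.random.default_rng(seed)
    candidates: list[NetworkModel] = []
    failures = 0
    for _ in range(n_train_networks):
        hidden = int(rng.integers(hidden_range[0], hidden_range[1] + 1))
        act_h = ACTIVATIONS[rng.integers(len(ACTIVATIONS))]
        act_o = ACTIVATIONS[rng.integers(len(ACTIVATIONS))]
        child = int(rng.integers(2 ** 31))
        try:
            m = train_mlp((X_tr, y_tr), hidden=hidden,
                          activations=(act_h, act_o), seed=child,
                          maxiter=maxiter, names=names)
        except (FloatingPointError, np.linalg.LinAlgError):
            failures += 1
            continue
        m.sos_validation = m.sos(X_val, y_val)
        candidates.append(m)
    if not candidates:
        raise AnnError(f"all {failures} trainings failed")
    candidates.sort(key=lambda m: m.sos_validation)
    return candidates[:n_retain]


@dataclass
class GsaReport:
    scores: dict[str, float]
    ranking: list[str] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = sorted(self.scores, key=self.scores.get, reverse=True)

    def dispensable(self) -> list[str]:
        """Inputs scoring 1 or lower: the network does no worse without them."""
        return [n for n, s in self.scores.items() if s <= 1.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "descriptor": self.ranking,
            "score": [self.scores[n] for n in self.ranking],
            "rank": range(1, len(self.ranking) + 1),
        })


def gsa(model: NetworkModel, data, names=None, split: str | None = None,
        retrain: bool = False, seed: int = 0) -> GsaReport:
    """Global sensitivity analysis of a trained network.

    Score of input j = SOS(input j replaced by its training-set mean) /
    SOS(full model). With ``retrain=True`` the reduced model is refit
    without the variable instead of mean-substituted (non-default variant).
    """
    names = tuple(names or model.input_names)
    X, y = as_xy(data, names=names, split=split)
    sos_full = model.sos(X, y)
    scores: dict[str, float] = {}
    degenerate = sos_full == 0.0
    for j, name in enumerate(names):
        Xj = X.copy()
        Xj[:, j] = X[:, j].mean()
        if retrain:
            keep = [i for i in range(len(names)) if i != j]
            sub = train_mlp((X[:, keep], y), hidden=model.hidden,
                            activations=(model.act_hidden, model.act_out),
                            seed=seed, names=[names[i] for i in keep])
            sos_j = sub.sos(X[:, keep], y)
        else:
            sos_j = model.sos(Xj, y)
        if degenerate:
            scores[name] = np.inf if sos_j > 0 else 1.0
        else:
            scores[name] = sos_j / sos_full
    return GsaReport(scores=scores, degenerate=degenerate)
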