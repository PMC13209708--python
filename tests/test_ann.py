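"""MLP training, automated architecture search, and GSA input importance."""

import numpy as np
import pytest

from sunqsar.ann import (
    AnnError,
    NetworkModel,
    automated_search,
    gsa,
    train_mlp,
)
from sunqsar.data import random_split
from sunqsar.mlr import fit_ols
from sunqsar.synthetic import SyntheticConfig, generate


def _r2(y, pred):
    return 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)


class TestTrainMlp:
    def test_linear_map_is_representable(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        m = train_mlp((x, 0.5 * x[:, 0]), hidden=1,
                      activations=("identity", "identity"), seed=0,
                      names=("x",))
        assert m.sos_train < 1e-6

    def test_constant_response(self):
        x = np.linspace(0, 1, 15).reshape(-1, 1)
        m = train_mlp((x, np.full(15, 3.7)), hidden=2, seed=1, names=("x",))
        assert m.sos_train == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(m.predict(x), 3.7, atol=1e-4)

    def test_fits_smooth_nonlinearity(self):
        # sin(3x) on [0, 2pi]: tanh hidden layer should reach R^2 > 0.95
        x = np.linspace(0, 2 * np.pi, 120).reshape(-1, 1)
        y = np.sin(3 * x[:, 0])
        best = max(
            _r2(y, train_mlp((x, y), hidden=10, activations=("tanh", "identity"),
                             seed=s, maxiter=2000, names=("x",)).predict(x))
            for s in range(3))
        assert best > 0.95

    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0] - X[:, 1]
        a = train_mlp((X, y), hidden=3, seed=7, names=("a", "b"))
        b = train_mlp((X, y), hidden=3, seed=7, names=("a", "b"))
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.standard_normal((10, 1))
        with pytest.raises(AnnError):
            train_mlp((X, X[:, 0]), hidden=0, names=("x",))
        with pytest.raises(AnnError):
            train_mlp((X, X[:, 0]), activations=("relu", "identity"),
                      names=("x",))


@pytest.fixture(scope="module")
def split_reference():
    ds = generate(SyntheticConfig(n=121, seed=7))
    return random_split(ds, {"train": 0.7, "test": 0.15,
                             "validation": 0.15}, seed=3)


class TestAutomatedSearch:
    def test_single_network(self, split_reference):
        nets = automated_search(split_reference, n_train_networks=1,
                                n_retain=1, seed=0)
        assert len(nets) == 1

    def test_retained_sorted_by_validation_sos(self, split_reference):
        nets = automated_search(split_reference, n_train_networks=12,
                                n_retain=5, seed=2)
        assert len(nets) == 5
        sos = [m.sos_validation for m in nets]
        assert sos == sorted(sos)

    def test_reproducible_bit_for_bit(self, split_reference):
        a = automated_search(split_reference, n_train_networks=8, n_retain=3,
                             seed=11)
        b = automated_search(split_reference, n_train_networks=8, n_retain=3,
                             seed=11)
        for ma, mb in zip(a, b):
            assert ma.hidden == mb.hidden
            assert (ma.act_hidden, ma.act_out) == (mb.act_hidden, mb.act_out)
            assert np.array_equal(ma.W1, mb.W1)
            assert ma.sos_validation == mb.sos_validation

    def test_retain_more_than_trained_rejected(self, split_reference):
        with pytest.raises(AnnError):
            automated_search(split_reference, n_train_networks=2, n_retain=3)

    def test_best_network_competitive_with_ols(self, split_reference):
        # an MLP can represent a linear map, so on linearly generated data
        # the search winner should be within 0.1 R^2 of OLS on the test set
        nets = automated_search(split_reference, n_train_networks=40,
                                n_retain=5, seed=5)
        te = split_reference.subset("test")
        X, y = te.descriptor_matrix(), te.response()
        ols = fit_ols(split_reference, split="train")
        assert _r2(y, nets[0].predict(X)) >= _r2(y, ols.predict(X)) - 0.1


class TestGsa:
    def test_ignored_input_scores_exactly_one(self, rng):
        X = rng.standard_normal((40, 2))
        y = 2 * X[:, 0]
        m = train_mlp((X, y), hidden=3, seed=0, names=("x1", "x2"))
        m.W1[:, 1] = 0.0  # sever all outgoing weights of x2
        rep = gsa(m, (X, y))
        assert rep.scores["x2"] == 1.0  # exact, not approximate

    def test_informative_versus_noise_input(self):
        # modest response noise keeps the full-model SOS away from zero so
        # the error ratio is stable
        gen = np.random.default_rng(10)
        X = gen.standard_normal((200, 2))
        y = 2 * X[:, 0] + 0.3 * gen.standard_normal(200)
        best = None
        for s in range(3):
            m = train_mlp((X, y), hidden=3, seed=s, maxiter=800,
                          names=("x1", "noise"))
            if best is None or m.sos_train < best.sos_train:
                best = m
        rep = gsa(best, (X, y))
        assert rep.scores["x1"] > 2
        assert rep.scores["noise"] == pytest.approx(1.0, abs=0.2)
        assert rep.ranking[0] == "x1"
        assert "noise" in rep.dispensable() or rep.scores["noise"] <= 1.2

    def test_duplicated_input_dilutes_importance(self, rng):
        x = rng.standard_normal(100)
        y = 2 * x
        single = train_mlp((x.reshape(-1, 1), y), hidden=3, seed=1,
                           maxiter=1000, names=("x",))
        dup = train_mlp((np.column_stack([x, x]), y), hidden=3, seed=1,
                        maxiter=1000, names=("x", "x_copy"))
        s_single = gsa(single, (x.reshape(-1, 1), y)).scores["x"]
        s_dup = gsa(dup, (np.column_stack([x, x]), y)).scores
        assert s_dup["x"] < s_single
        assert s_dup["x_copy"] < s_single

    def test_degenerate_zero_error_flagged(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        m = train_mlp((x, np.zeros(10)), hidden=1,
                      activations=("identity", "identity"), seed=0,
                      names=("x",))
        # force an exactly-zero-error model
        m.W1[:] = 0; m.b1[:] = 0; m.W2[:] = 0; m.b2[:] = 0
        m.y_min, m.y_range = 0.0, 1.0
        rep = gsa(m, (x, np.zeros(10)))
        assert rep.degenerate
        assert all(s == 1.0 for s in rep.scores.values())
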