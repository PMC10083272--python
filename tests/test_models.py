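import numpy as np
import pytest

from anthomap.models import (
    GaConfig,
    evaluate,
    fit_elm,
    fit_ga_elm,
    fit_ga_lssvm,
    fit_lssvm,
    ga_optimize,
    r2_score,
    split_dataset,
)


# ------------------------------------------------------------------ split

def test_split_180_stratified_gives_126_54():
    strata = np.repeat(np.arange(6), 30)
    y = np.random.default_rng(0).normal(size=180)
    tr, te = split_dataset(np.zeros((180, 2)), y, strata, seed=1)
    assert len(tr) == 126 and len(te) == 54
    # each cell splits 21/9
    for s in range(6):
        cell = np.flatnonzero(strata == s)
        assert np.isin(cell, tr).sum() == 21


def test_split_is_partition_and_deterministic():
    y = np.arange(10.0)
    tr1, te1 = split_dataset(np.zeros((10, 1)), y, seed=4)
    tr2, te2 = split_dataset(np.zeros((10, 1)), y, seed=4)
    assert len(tr1) == 7 and len(te1) == 3
    np.testing.assert_array_equal(tr1, tr2)
    assert set(tr1) | set(te1) == set(range(10))
    assert set(tr1) & set(te1) == set()


def test_split_singleton_stratum_goes_to_training():
    strata = np.array([0] * 9 + [1])
    with pytest.warns(UserWarning):
        tr, te = split_dataset(np.zeros((10, 1)), np.zeros(10), strata, seed=0)
    assert 9 in tr


# -------------------------------------------------------------------- ELM

def test_elm_interpolates_when_hidden_geq_n():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(40, 4)), rng.normal(size=40)
    m = fit_elm(X, y, n_hidden=90, seed=1)
    assert np.sqrt(np.mean((m.predict(X) - y) ** 2)) < 1e-6


def test_elm_residual_orthogonal_to_hidden_space():
    rng = np.random.default_rng(1)
    X, y = rng.normal(size=(100, 3)), rng.normal(size=100)
    m = fit_elm(X, y, n_hidden=20, seed=2)
    H = m.hidden(X)
    res = y - H @ m.output_weights
    assert np.abs(H.T @ res).max() < 1e-8


def test_elm_zero_target_gives_zero_predictions():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    m = fit_elm(X, np.zeros(30), n_hidden=10, seed=0)
    np.testing.assert_allclose(m.predict(X), 0.0, atol=1e-10)


def test_elm_learns_linear_map():
    rng = np.random.default_rng(3)
    X = rng.uniform(-1, 1, size=(200, 3))
    y = 3.0 * X[:, 0] + 0.01 * rng.normal(size=200)
    Xte = rng.uniform(-1, 1, size=(100, 3))
    yte = 3.0 * Xte[:, 0]
    m = fit_elm(X, y, n_hidden=90, seed=4)
    assert np.sqrt(np.mean((m.predict(Xte) - yte) ** 2)) < 0.05


def test_elm_rejects_nonfinite():
    X = np.array([[1.0, np.nan]])
    with pytest.raises(ValueError):
        fit_elm(X, np.array([1.0]))


# ----------------------------------------------------------------- LS-SVM

def test_lssvm_near_constant_in_flat_kernel_limit():
    """With gamma at its lower bound and tiny feature scale the RBF kernel
    is ~all-ones and predictions collapse to the target mean."""
    rng = np.random.default_rng(4)
    X = 0.001 * rng.normal(size=(30, 2))
    y = rng.normal(2.0, 1.0, size=30)
    m = fit_lssvm(X, y, C=1.0, gamma=0.01)
    np.testing.assert_allclose(m.predict(X), y.mean(), atol=0.01)


def test_lssvm_interpolates_at_large_C():
    X = np.linspace(-1, 1, 5)[:, None]
    y = np.array([0.0, 1.0, -1.0, 2.0, 0.5])
    m = fit_lssvm(X, y, C=100.0, gamma=10.0)
    assert np.abs(m.predict(X) - y).max() < 0.05


def test_lssvm_matches_dense_solve():
    rng = np.random.default_rng(5)
    X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
    C, gamma = 5.0, 0.5
    m = fit_lssvm(X, y, C, gamma)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * d2)
    A = np.block([[np.zeros((1, 1)), np.ones((1, 20))],
                  [np.ones((20, 1)), K + np.eye(20) / C]])
    sol = np.linalg.solve(A, np.concatenate([[0.0], y]))
    assert m.bias == pytest.approx(sol[0], abs=1e-8)
    np.testing.assert_allclose(m.support_values, sol[1:], atol=1e-8)


def test_lssvm_bounds_enforced():
    with pytest.raises(ValueError):
        fit_lssvm(np.zeros((5, 1)), np.zeros(5), C=0.001, gamma=1.0)


# --------------------------------------------------------------------- GA

def test_ga_sphere_benchmark():
    cfg = GaConfig(bounds=np.array([[-5.0, 5.0], [-5.0, 5.0]]),
                   population=20, generations=200, seed=0)
    best, path = ga_optimize(lambda g: float(g @ g), cfg)
    assert path[-1] < 1e-2
    assert all(a >= b for a, b in zip(path, path[1:]))  # monotone by elitism
    assert np.all(np.abs(best) <= 5.0)


def test_ga_constant_fitness_returns_valid_genome():
    cfg = GaConfig(bounds=np.array([[0.0, 1.0]]), population=6, generations=10, seed=1)
    best, path = ga_optimize(lambda g: 1.0, cfg)
    assert 0.0 <= best[0] <= 1.0
    assert path == [1.0] * 10


def test_ga_respects_bounds_throughout():
    seen = []

    def fitness(g):
        seen.append(g.copy())
        return float(np.sum(g**2))

    cfg = GaConfig(bounds=np.array([[-1.0, 2.0], [0.5, 3.0]]),
                   population=8, generations=20, seed=2)
    ga_optimize(fitness, cfg)
    arr = np.array(seen)
    assert np.all(arr[:, 0] >= -1.0) and np.all(arr[:, 0] <= 2.0)
    assert np.all(arr[:, 1] >= 0.5) and np.all(arr[:, 1] <= 3.0)


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GaConfig(bounds=np.array([[1.0, 0.0]]))
    with pytest.raises(ValueError):
        GaConfig(bounds=np.array([[0.0, 1.0]]), population=1)


# ------------------------------------------------------------ GA wrappers

def test_ga_elm_beats_median_random_restart():
    rng = np.random.default_rng(6)
    X = rng.uniform(-1, 1, size=(60, 3))
    y = np.sin(2 * X[:, 0]) + 0.5 * X[:, 1] + 0.05 * rng.normal(size=60)
    model, path = fit_ga_elm(X, y, n_hidden=15, generations=15, seed=0)
    assert all(a >= b for a, b in zip(path, path[1:]))
    from anthomap.models import _cv_rmse

    randoms = []
    for s in range(20):
        r = np.random.default_rng(100 + s)
        W = r.uniform(-1, 1, size=(3, 15))
        b = r.uniform(-1, 1, size=15)

        def fp(Xt, yt, Xv, W=W, b=b):
            return fit_elm(Xt, yt, W, b).predict(Xv)

        randoms.append(_cv_rmse(fp, X, y, 5, 0))
    assert path[-1] <= np.median(randoms)


def test_ga_lssvm_returns_params_in_bounds():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 2))
    y = X[:, 0] ** 2 + 0.1 * rng.normal(size=40)
    model, path = fit_ga_lssvm(X, y, generations=10, seed=1)
    assert 0.01 <= model.C <= 100.0
    assert 0.01 <= model.gamma <= 100.0
    assert all(a >= b for a, b in zip(path, path[1:]))


# ---------------------------------------------------------------- metrics

class _Identity:
    def predict(self, X):
        return np.asarray(X)[:, 0]


def test_evaluate_perfect_predictions():
    y = np.array([1.0, 2.0, 3.0])
    rep = evaluate(_Identity(), y[:, None], y, y[:, None], y)
    assert rep.r2_train == 1.0 and rep.rmse_test == 0.0


def test_evaluate_mean_predictor_gives_zero_r2():
    y = np.array([1.0, 2.0, 3.0])
    pred = np.full(3, 2.0)

    class _Mean:
        def predict(self, X):
            return pred

    rep = evaluate(_Mean(), y[:, None], y, y[:, None], y)
    assert rep.r2_test == pytest.approx(0.0)


def test_evaluate_hand_computed():
    y = np.array([1.0, 2.0, 3.0])
    pred = np.array([1.0, 2.0, 4.0])

    class _Fixed:
        def predict(self, X):
            return pred

    rep = evaluate(_Fixed(), y[:, None], y, y[:, None], y)
    assert rep.rmse_test == pytest.approx(np.sqrt(1 / 3), abs=1e-9)
    assert rep.r2_test == pytest.approx(0.5, abs=1e-12)


def test_r2_undefined_for_zero_variance():
    assert np.isnan(r2_score(np.ones(5), np.ones(5)))
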