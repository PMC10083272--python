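"""Regression models and genetic-algorithm hyperparameter search.

Two non-linear regressors predict anthocyanin content from spectral
features:

* **ELM** — a single-hidden-layer feedforward network whose hidden
  weights/offsets are fixed (randomly, or by GA search) and whose output
  weights are the minimum-norm least-squares solution, so there is no
  iterative training. Hidden width defaults to 90 sigmoid neurons.
* **LS-SVM** — kernel ridge-style regression with an RBF kernel
  k(u, v) = exp(-gamma * ||u - v||^2), solved as one regularized linear
  system with bias; governed by C and gamma, both searched in
  [0.01, 100].

The GA is real-coded: tournament selection (size 2), arithmetic
crossover, Gaussian mutation with an exponentially annealed scale,
clipping to the gene bounds, and elitism of 1. Model fitness is 5-fold
cross-validated RMSE on the training set, which penalizes the
interpolating solutions an ELM with 90 neurons can reach on small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

GA_BOUNDS_LOG_C = (-2.0, 2.0)  # log10 of C and gamma: [0.01, 100]


# ---------------------------------------------------------------- splitting

def split_dataset(
    X: np.ndarray,
    y: np.ndarray,
    strata: Sequence | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
):
    """Stratified random partition into training and testing sets.

    Each stratum (e.g. variety x stage cell) is split as close to the
    requested ratio as integer rounding allows; strata with a single
    member go wholly to training with a warning. Returns
    ``(train_idx, test_idx)`` index arrays — disjoint and exhaustive.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        if members.size < 2:
            warnings.warn(f"stratum {s!r} has < 2 members; assigned to training", stacklevel=2)
            train.extend(members)
            continue
        perm = rng.permutation(members)
        n_tr = int(round(train_fraction * members.size))
        n_tr = min(max(n_tr, 1), members.size - 1)
        train.extend(perm[:n_tr])
        test.extend(perm[n_tr:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


# ---------------------------------------------------------------------- ELM

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40.0, 40.0)))


@dataclass
class ElmModel:
    """Extreme learning machine: fixed hidden layer, solved output layer."""

    input_weights: np.ndarray  # (n_features, n_hidden)
    offsets: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(X, float) @ self.input_weights + self.offsets)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.hidden(X) @ self.output_weights


def fit_elm(
    X: np.ndarray,
    y: np.ndarray,
    input_weights: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
    n_hidden: int = 90,
    seed: int = 0,
) -> ElmModel:
    """Solve the ELM output weights in closed form.

    With given hidden parameters the output weights are the minimum-norm
    least-squares solution of H beta = y, H = sigmoid(X W + b); if the
    hidden parameters are omitted they are drawn uniformly from [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or targets")
    if input_weights is None or offsets is None:
        rng = np.random.default_rng(seed)
        input_weights = rng.uniform(-1, 1, size=(X.shape[1], n_hidden))
        offsets = rng.uniform(-1, 1, size=n_hidden)
    H = _sigmoid(X @ input_weights + offsets)
    # pseudoinverse with a small singular-value floor: directions of the
    # hidden space that the training data barely excites carry no signal
    # and would otherwise receive huge cancelling output weights
    beta, *_ = np.linalg.lstsq(H, y, rcond=1e-8)
    return ElmModel(np.asarray(input_weights, float), np.asarray(offsets, float), beta)


# ------------------------------------------------------------------- LS-SVM

@dataclass
class LssvmModel:
    """Least-squares SVM regression with RBF kernel."""

    C: float
    gamma: float
    support_values: np.ndarray  # alpha, one per training row
    bias: float
    X_train: np.ndarray

    def __post_init__(self) -> None:
        if not (0.01 <= self.C <= 100 and 0.01 <= self.gamma <= 100):
            raise ValueError("C and gamma must lie in [0.01, 100]")

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-self.gamma * np.maximum(d2, 0.0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = self._kernel(np.asarray(X, float), self.X_train)
        return K @ self.support_values + self.bias


def fit_lssvm(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> LssvmModel:
    """Solve the LS-SVM linear system

        [[0, 1^T], [1, K + I/C]] [b; alpha] = [0; y].

    A singular system gets one 1e-10 jitter retry before erroring.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    model = LssvmModel(C, gamma, np.zeros(n), 0.0, X)
    K = model._kernel(X, X)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / C
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        A[1:, 1:] += 1e-10 * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    model.bias = float(sol[0])
    model.support_values = sol[1:]
    return model


# ----------------------------------------------------------------------- GA

@dataclass
class GaConfig:
    """Real-coded GA settings; bounds is a (n_genes, 2) array."""

    bounds: np.ndarray
    population: int = 20
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]) or not np.all(
            np.isfinite(self.bounds)
        ):
            raise ValueError("bounds must be finite with low < high")


def ga_optimize(fitness: Callable[[np.ndarray], float], config: GaConfig):
    """Minimize ``fitness`` over the bounded box.

    Returns ``(best_genome, best_path)`` where ``best_path`` is the
    best-ever fitness per generation — non-increasing by elitism. The
    Gaussian mutation scale anneals exponentially from 10% to about 0.5%
    of each gene's range over the run.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    span = hi - lo
    n_genes = lo.size
    pop = rng.uniform(lo, hi, size=(config.population, n_genes))
    fit = np.array([fitness(g) for g in pop])
    best_i = int(np.argmin(fit))
    best_genome, best_fit = pop[best_i].copy(), float(fit[best_i])
    path = []
    for gen in range(config.generations):
        sigma = 0.10 * span * np.exp(-3.0 * gen / max(config.generations - 1, 1))
        # tournament selection, size 2
        a = rng.integers(0, config.population, size=config.population)
        b = rng.integers(0, config.population, size=config.population)
        parents = pop[np.where(fit[a] <= fit[b], a, b)]
        children = parents.copy()
        for i in range(0, config.population - 1, 2):
            if rng.random() < config.crossover_rate:
                lam = rng.random(n_genes)
                p1, p2 = parents[i].copy(), parents[i + 1].copy()
                children[i] = lam * p1 + (1 - lam) * p2
                children[i + 1] = (1 - lam) * p1 + lam * p2
        mut = rng.random(children.shape) < config.mutation_rate
        children = children + mut * rng.normal(0.0, sigma, size=children.shape)
        np.clip(children, lo, hi, out=children)
        children[0] = best_genome  # elitism of 1
        pop = children
        fit = np.array([fitness(g) for g in pop])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_genome = pop[gen_best].copy()
        path.append(best_fit)
    return best_genome, path


def _cv_rmse(fit_predict, X, y, folds: int, seed: int) -> float:
    """K-fold CV RMSE of a fit(X, y) -> predict(X) factory."""
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    edges = np.linspace(0, n, folds + 1).astype(int)
    sq = 0.0
    for f in range(folds):
        va = order[edges[f] : edges[f + 1]]
        tr = np.setdiff1d(order, va)
        pred = fit_predict(X[tr], y[tr], X[va])
        sq += float(np.sum((y[va] - pred) ** 2))
    return np.sqrt(sq / n)


def fit_ga_elm(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 90,
    generations: int = 300,
    population: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[ElmModel, list[float]]:
    """GA search over the ELM hidden weights and offsets.

    The genome concatenates the (n_features x n_hidden) weight matrix and
    the offsets, all in [-1, 1]; fitness is 5-fold CV RMSE on the
    training set; the returned model is refit on all training rows with
    the best genome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    nf = X.shape[1]
    n_genes = nf * n_hidden + n_hidden

    def unpack(g):
        return g[: nf * n_hidden].reshape(nf, n_hidden), g[nf * n_hidden :]

    def fitness(g):
        W, b = unpack(g)

        def fp(Xt, yt, Xv):
            return fit_elm(Xt, yt, W, b).predict(Xv)

        return _cv_rmse(fp, X, y, cv_folds, seed)

    config = GaConfig(
        bounds=np.tile([-1.0, 1.0], (n_genes, 1)),
        population=population,
        generations=generations,
        seed=seed,
    )
    best, path = ga_optimize(fitness, config)
    W, b = unpack(best)
    return fit_elm(X, y, W, b), path


def fit_ga_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    generations: int = 200,
    population: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[LssvmModel, list[float]]:
    """GA search over (C, gamma) in [0.01, 100]^2 (log10-coded genes);
    fitness is 5-fold CV RMSE; final refit on the full training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    def fitness(g):
        C, gamma = 10.0 ** g[0], 10.0 ** g[1]

        def fp(Xt, yt, Xv):
            return fit_lssvm(Xt, yt, C, gamma).predict(Xv)

        return _cv_rmse(fp, X, y, cv_folds, seed)

    config = GaConfig(
        bounds=np.array([GA_BOUNDS_LOG_C, GA_BOUNDS_LOG_C]),
        population=population,
        generations=generations,
        seed=seed,
    )
    best, path = ga_optimize(fitness, config)
    model = fit_lssvm(X, y, 10.0 ** best[0], 10.0 ** best[1])
    return model, path


# ----------------------------------------------------------------- metrics

@dataclass
class EvalReport:
    """Train/test determination coefficients and RMSEs (mg/g)."""

    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    n_train: int
    n_test: int
    pearson2_train: float = np.nan
    pearson2_test: float = np.nan

    def as_dict(self) -> dict:
        return {
            "r2_train": self.r2_train, "r2_test": self.r2_test,
            "rmse_train": self.rmse_train, "rmse_test": self.rmse_test,
            "n_train": self.n_train, "n_test": self.n_test,
        }


def r2_score(y: np.ndarray, pred: np.ndarray) -> float:
    """R^2 = 1 - SS_res/SS_tot about the evaluated set's own mean;
    NaN if the set has zero variance."""
    y = np.asarray(y, float).ravel()
    pred = np.asarray(pred, float).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def rmse(y: np.ndarray, pred: np.ndarray) -> float:
    y = np.asarray(y, float).ravel()
    pred = np.asarray(pred, float).ravel()
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def _pearson2(y, pred) -> float:
    y, pred = np.asarray(y, float).ravel(), np.asarray(pred, float).ravel()
    if np.std(y) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(y, pred)[0, 1] ** 2)


def evaluate(model, X_train, y_train, X_test, y_test) -> EvalReport:
    """Standard chemometric report: R2c/R2p and RMSEC/RMSEP, with squared
    Pearson correlations carried alongside."""
    if len(y_train) == 0 or len(y_test) == 0:
        raise ValueError("evaluation sets must be non-empty")
    pt = model.predict(np.asarray(X_train, float))
    pv = model.predict(np.asarray(X_test, float))
    return EvalReport(
        r2_train=r2_score(y_train, pt),
        r2_test=r2_score(y_test, pv),
        rmse_train=rmse(y_train, pt),
        rmse_test=rmse(y_test, pv),
        n_train=len(y_train),
        n_test=len(y_test),
        pearson2_train=_pearson2(y_train, pt),
        pearson2_test=_pearson2(y_test, pv),
    )
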