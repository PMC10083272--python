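"""Characteristic-wavelength selection: SPA and CARS.

Both engines operate on SNV-pretreated mean ROI spectra (n samples x p
bands) with wet-chemistry contents as the response.

SPA (successive projections algorithm) grows, from every candidate start
band, a chain of minimally collinear bands by repeatedly projecting the
remaining columns onto the orthogonal complement of the chain and taking
the maximum-norm projection; candidate subsets are scored by the RMSE of
an ordinary least-squares fit on a holdout split.

CARS (competitive adaptive reweighted sampling) runs Monte-Carlo
sampling rounds: each round fits PLS on a random calibration subset and
competitively resamples the surviving bands with probability
proportional to |PLS regression coefficient|, the retained count forced
down an exponential decline from p to 2 across the rounds; the surviving
set with minimum 10-fold cross-validated RMSE wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, cross_val_predict

from .types import SpectralMatrix


@dataclass
class SelectionResult:
    """Outcome of a variable-selection engine."""

    method: str  # "SPA" | "CARS" | "SAE"
    indices: np.ndarray  # selected band indices, sorted ascending
    wavelengths: np.ndarray  # nm, parallel to indices
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0) or self.indices.min() < 0
        ):
            raise ValueError("indices must be unique, sorted, non-negative")

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)


def _as_xy(X, y):
    if isinstance(X, SpectralMatrix):
        wavelengths = X.wavelengths
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        wavelengths = np.arange(X.shape[1], dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    return X, y, wavelengths


def _ols_rmse(X_tr, y_tr, X_va, y_va) -> float:
    """Validation RMSE of an intercept-augmented least-squares fit."""
    A = np.column_stack([np.ones(len(X_tr)), X_tr])
    coef, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
    pred = np.column_stack([np.ones(len(X_va)), X_va]) @ coef
    return float(np.sqrt(np.mean((y_va - pred) ** 2)))


def spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Projection chain from ``start``: at each step every remaining
    column is deflated by the newest chain member and the largest
    remaining norm joins the chain. Columns are mean-centered first."""
    Xc = X - X.mean(axis=0)
    p = Xc.shape[1]
    chain = [start]
    work = Xc.copy()
    for _ in range(1, min(max_vars, p)):
        k = chain[-1]
        xk = work[:, k]
        nk = xk @ xk
        if nk < 1e-12:
            warnings.warn("SPA chain truncated: degenerate projections", stacklevel=2)
            break
        work = work - np.outer(xk, xk @ work) / nk
        norms = np.einsum("ij,ij->j", work, work)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-12:
            warnings.warn("SPA chain truncated: degenerate projections", stacklevel=2)
            break
        chain.append(nxt)
    return chain


def spa_select(
    X,
    y,
    max_vars: int = 25,
    validation: float = 1 / 3,
    seed: int = 0,
    starts: np.ndarray | None = None,
) -> SelectionResult:
    """Successive projections algorithm.

    Every column (or ``starts``) seeds a chain; each (start, k) prefix is
    scored by holdout OLS RMSE and the global minimizer is returned. The
    diagnostics carry the RMSE-vs-k path of the winning start, which
    typically falls in the ladder shape characteristic of SPA.
    """
    X, y, wavelengths = _as_xy(X, y)
    n, p = X.shape
    max_vars = min(max_vars, p, max(1, n - 3))
    if p == 1:
        return SelectionResult("SPA", np.array([0]), wavelengths[:1],
                               {"rmse_path": [], "k": 1})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_va = max(1, int(round(validation * n)))
    va, tr = perm[:n_va], perm[n_va:]
    if starts is None:
        starts = np.arange(p)

    best_rmse, cols = np.inf, [int(starts[0])]
    for s in starts:
        chain = spa_chain(X, int(s), max_vars)
        for k in range(1, len(chain) + 1):
            rmse = _ols_rmse(X[tr][:, chain[:k]], y[tr], X[va][:, chain[:k]], y[va])
            if rmse < best_rmse:
                best_rmse, cols = rmse, list(chain[:k])
    win_chain = spa_chain(X, cols[0], max_vars)
    path = [
        _ols_rmse(X[tr][:, win_chain[:k]], y[tr], X[va][:, win_chain[:k]], y[va])
        for k in range(1, len(win_chain) + 1)
    ]
    rmse = best_rmse
    idx = np.sort(np.asarray(cols))
    return SelectionResult(
        "SPA", idx, wavelengths[idx],
        {"rmse_path": path, "k": len(cols), "best_rmse": rmse, "start": int(cols[0])},
    )


def _edf_counts(p: int, n_runs: int) -> np.ndarray:
    """Retained-count schedule: ratio r_i = a*exp(-k*i) with r_1 = 1 and
    r_{n_runs} = 2/p, so the path opens at p and closes at 2. A single
    run keeps the ratio at 1 (plain weighted resampling of all bands)."""
    if n_runs == 1:
        return np.array([p])
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    return np.maximum(2, np.round(a * np.exp(-k * i) * p)).astype(int)


def _pick_ncomp(X, y, max_components: int, seed: int) -> int:
    """Inner 3-fold CV over the PLS component count."""
    n, p = X.shape
    # component count is capped by the smallest CV training fold
    hi = int(min(max_components, p, n - int(np.ceil(n / 3)) - 1))
    if hi <= 1:
        return 1
    cv = KFold(3, shuffle=True, random_state=seed)
    best, best_rmse = 1, np.inf
    for nc in range(1, hi + 1):
        pred = cross_val_predict(PLSRegression(nc, scale=False), X, y, cv=cv).ravel()
        rmse = np.sqrt(np.mean((y - pred) ** 2))
        if rmse < best_rmse - 1e-12:
            best, best_rmse = nc, rmse
    return best


def cars_select(
    X,
    y,
    n_runs: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
    mc_fraction: float = 0.8,
    max_components: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Diagnostics: ``rmsecv_path`` (one 10-fold RMSECV per run),
    ``count_path`` (EDF-forced retained counts, non-increasing from p)
    and ``best_run`` (1-based index of the winning round).
    """
    X, y, wavelengths = _as_xy(X, y)
    n, p = X.shape
    if n < 2 * cv_folds:
        raise ValueError(f"need n >= {2 * cv_folds} samples for {cv_folds}-fold RMSECV")
    rng = np.random.default_rng(seed)
    counts = _edf_counts(p, n_runs)
    survivors = np.arange(p)
    n_cal = max(2, int(round(mc_fraction * n)))
    rmsecv_path, sets = [], []
    for i in range(n_runs):
        cal = rng.choice(n, size=n_cal, replace=False)
        Xs = X[np.ix_(cal, survivors)]
        ncomp = _pick_ncomp(Xs, y[cal], max_components, seed)
        pls = PLSRegression(n_components=min(ncomp, Xs.shape[1]), scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xs, y[cal])
        w = np.abs(pls.coef_).ravel() + 1e-12
        n_keep = min(counts[i], survivors.size)
        # adaptive reweighted sampling: competitive draw without
        # replacement, weight proportional to |PLS coefficient|
        survivors = np.sort(rng.choice(survivors, size=n_keep, replace=False, p=w / w.sum()))
        ncomp_cv = int(min(ncomp, survivors.size, n - int(np.ceil(n / cv_folds)) - 1))
        cv = KFold(cv_folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = cross_val_predict(
                PLSRegression(max(1, ncomp_cv), scale=False), X[:, survivors], y, cv=cv
            ).ravel()
        rmsecv_path.append(float(np.sqrt(np.mean((y - pred) ** 2))))
        sets.append(survivors.copy())
    best_run = int(np.argmin(rmsecv_path))
    idx = sets[best_run]
    return SelectionResult(
        "CARS", idx, wavelengths[idx],
        {
            "rmsecv_path": rmsecv_path,
            "count_path": counts.tolist(),
            "best_run": best_run + 1,
        },
    )
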