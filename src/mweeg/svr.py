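"""ε-insensitive support vector regression, grid search, and the 5-model family.

The regression function is f(x) = x'β + β0 (or its kernelized form); fitting
minimizes C·Σ V_ε(y_i − f(x_i)) + ½‖β‖² where V_ε is the ε-insensitive loss.
Kernels: linear and RBF k(x, x') = exp(−γ‖x−x'‖²).  The optimum is delegated
to libsvm via scikit-learn; the package contract is the minimizer of the
objective, not a particular algorithm.

Hyperparameter search is an exhaustive grid over (C, ε) scored by k-fold
cross-validated mean squared error, with γ fixed at 1/n_features (the common
solver default; the grids default to powers of two).  The model family:

* Model 1 / 3 — RBF / linear SVR at each kernel's best-CV threshold set;
* Model 2 / 4 — same, restricted to sets using at most ``electrode_budget``
  (default 9) electrodes;
* Model 5 — ordinary least-squares simple regression on the single best
  predictor.

Cross-validation precomputes the kernel matrix once per predictor set, so the
(C, ε) sweep costs little beyond the libsvm solves themselves.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .dataset import ModelingDataset
from .exceptions import ConfigurationError, StructuralError
from .selection import PredictorSet

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_EPSILON_GRID",
    "SvrHyperparams",
    "SvrModel",
    "CvResult",
    "FittedModel",
    "ModelFamily",
    "svr_fit",
    "svr_predict",
    "svr_objective",
    "grid_search_cv",
    "fit_model_family",
]

DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-4, 3))        # 0.0625 .. 4
DEFAULT_EPSILON_GRID = tuple(2.0 ** k for k in range(-6, 2))  # 0.015625 .. 2


@dataclass(frozen=True)
class SvrHyperparams:
    C: float
    epsilon: float
    gamma: float | None = None   # ignored for the linear kernel

    def validate(self, kernel: str) -> None:
        if self.C <= 0:
            raise ConfigurationError("C: must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon: must be >= 0")
        if kernel == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ConfigurationError("gamma: must be > 0 for the rbf kernel")


@dataclass
class SvrModel:
    """A fitted ε-SVR: kernel, hyperparameters, and the dual solution.

    Predictions are computed from the stored dual coefficients u = α − α*
    over the retained training samples: f(x) = Σ u_i k(x_i, x) + β₀.
    """

    kernel: str                       # "linear" | "rbf"
    hyperparams: SvrHyperparams
    feature_names: tuple[str, ...]
    support_vectors: np.ndarray       # training rows with nonzero u
    dual_coef: np.ndarray             # u at the support rows
    b: float

    @property
    def coef(self) -> np.ndarray:
        """Primal weight vector β (linear kernel only)."""
        if self.kernel != "linear":
            raise StructuralError("primal coefficients exist only for linear kernel")
        return self.support_vectors.T @ self.dual_coef

    @property
    def intercept(self) -> float:
        return float(self.b)

    @property
    def _gamma(self) -> float | None:
        return self.hyperparams.gamma if self.kernel == "rbf" else None


def svr_fit(X: np.ndarray, y: np.ndarray, kernel: str, hp: SvrHyperparams,
            feature_names: tuple[str, ...] | None = None,
            tol: float = 1e-8) -> SvrModel:
    """Fit ε-SVR to (X, y); returns the objective's minimizer."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigurationError("X: need a non-empty 2-D predictor matrix")
    if X.shape[0] != len(y):
        raise ConfigurationError("X/y: row counts differ")
    if kernel not in ("linear", "rbf"):
        raise ConfigurationError(f"kernel: unknown kind {kernel!r}")
    hp.validate(kernel)
    gamma = hp.gamma if kernel == "rbf" else (hp.gamma or 1.0)
    est = SVR(kernel=kernel, C=hp.C, epsilon=hp.epsilon, gamma=gamma,
              tol=tol, max_iter=-1, cache_size=200)
    est.fit(X, y)
    u = np.zeros(len(y))
    u[est.support_] = np.asarray(est.dual_coef_).ravel()
    b = float(np.asarray(est.intercept_).ravel()[0])
    K = _kernel_matrix(X, X, kernel, gamma if kernel == "rbf" else None)
    u, b = _kkt_refine(K, y, hp.C, hp.epsilon, u, b)
    keep = np.abs(u) > 1e-12
    names = feature_names or tuple(f"x{i}" for i in range(X.shape[1]))
    return SvrModel(kernel=kernel, hyperparams=hp, feature_names=tuple(names),
                    support_vectors=X[keep].copy(), dual_coef=u[keep].copy(),
                    b=b)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str,
                   gamma: float | None) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def _primal_value(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                  u: np.ndarray, b: float) -> float:
    f = K @ u + b
    loss = np.maximum(np.abs(y - f) - epsilon, 0.0).sum()
    return float(C * loss + 0.5 * u @ K @ u)


def _kkt_refine(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                u: np.ndarray, b: float) -> tuple[np.ndarray, float]:
    """One exact Newton step on the active set identified by the solver.

    libsvm terminates on a dual-gradient tolerance, which can leave the
    objective a few 1e-6 above the optimum.  Holding the bound-active
    coordinates at ±C and zeros at 0, the stationarity conditions of the free
    coordinates plus the equality constraint form a linear system; its
    solution is accepted only if feasible and not worse in primal value.
    """
    tol = max(C * 1e-6, 1e-12)
    at_bound = np.abs(np.abs(u) - C) < tol
    zero = np.abs(u) < tol
    free = ~(at_bound | zero)
    if not free.any():
        return u, b
    idx = np.flatnonzero(free)
    fixed = np.where(at_bound, np.sign(u) * C, 0.0)
    nf = len(idx)
    A = np.zeros((nf + 1, nf + 1))
    rhs = np.zeros(nf + 1)
    A[:nf, :nf] = K[np.ix_(idx, idx)]
    A[:nf, nf] = 1.0
    A[nf, :nf] = 1.0
    rhs[:nf] = (y[idx] - epsilon * np.sign(u[idx])
                - K[np.ix_(idx, np.flatnonzero(~free))] @ fixed[~free])
    rhs[nf] = -fixed[~free].sum()
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return u, b
    u_new = fixed.copy()
    u_new[idx] = sol[:nf]
    b_new = float(sol[nf])
    if (np.abs(u_new) > C + 1e-12).any():
        return u, b
    if _primal_value(K, y, C, epsilon, u_new, b_new) \
            <= _primal_value(K, y, C, epsilon, u, b):
        return u_new, b_new
    return u, b


def svr_predict(model: SvrModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise StructuralError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns; model expects "
            f"{len(model.feature_names)}")
    if len(model.support_vectors) == 0:
        return np.full(X.shape[0], model.b)
    k = _kernel_matrix(X, model.support_vectors, model.kernel, model._gamma)
    return k @ model.dual_coef + model.b


def svr_objective(model: SvrModel, X: np.ndarray, y: np.ndarray) -> float:
    """Primal objective C·Σ V_ε(residual) + ½‖β‖² at the fitted solution.

    ‖β‖² is evaluated in the kernel's feature space from the dual
    coefficients, so the value is exact for both kernels.
    """
    hp = model.hyperparams
    resid = np.abs(y - svr_predict(model, X))
    loss = np.maximum(resid - hp.epsilon, 0.0).sum()
    sv = model.support_vectors
    k_sv = _kernel_matrix(sv, sv, model.kernel, model._gamma) \
        if len(sv) else np.zeros((0, 0))
    norm2 = float(model.dual_coef @ k_sv @ model.dual_coef)
    return hp.C * float(loss) + 0.5 * norm2


@dataclass
class CvResult:
    """Grid-search outcome: per-candidate mean CV MSE and the winner."""

    candidates: tuple[SvrHyperparams, ...]
    mean_mse: np.ndarray
    best_index: int
    k_folds: int
    seed: int

    @property
    def best(self) -> SvrHyperparams:
        return self.candidates[self.best_index]

    @property
    def best_mse(self) -> float:
        return float(self.mean_mse[self.best_index])


def _make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def grid_search_cv(X: np.ndarray, y: np.ndarray, kernel: str,
                   grid: tuple[SvrHyperparams, ...] | None = None,
                   k_folds: int = 10, seed: int = 0,
                   c_grid: tuple[float, ...] = DEFAULT_C_GRID,
                   epsilon_grid: tuple[float, ...] = DEFAULT_EPSILON_GRID,
                   gamma: float | None = None) -> CvResult:
    """Exhaustive (C, ε) grid search scored by k-fold CV mean squared error.

    Folds are as equal in size as possible (random row partition under
    *seed*, shared across candidates).  γ defaults to 1/n_features.  Ties go
    to the first candidate in enumeration order (C outer, ε inner).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k_folds < 2:
        raise ConfigurationError("k_folds: must be >= 2")
    if k_folds > n:
        raise ConfigurationError("k_folds: cannot exceed the number of samples")
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    if grid is None:
        grid = tuple(SvrHyperparams(C=c, epsilon=e, gamma=gamma)
                     for c in c_grid for e in epsilon_grid)
    else:
        grid = tuple(SvrHyperparams(hp.C, hp.epsilon, hp.gamma or gamma)
                     for hp in grid)
    if not grid:
        raise ConfigurationError("grid: must contain at least one candidate")

    folds = _make_folds(n, k_folds, seed)
    K = _kernel_matrix(X, X, kernel, gamma if kernel == "rbf" else None)
    mean_mse = np.zeros(len(grid))
    for ci, hp in enumerate(grid):
        hp.validate(kernel)
        fold_mse = []
        for te in folds:
            tr = np.setdiff1d(np.arange(n), te, assume_unique=False)
            est = SVR(kernel="precomputed", C=hp.C, epsilon=hp.epsilon)
            est.fit(K[np.ix_(tr, tr)], y[tr])
            pred = est.predict(K[np.ix_(te, tr)])
            fold_mse.append(float(np.mean((y[te] - pred) ** 2)))
        mean_mse[ci] = np.mean(fold_mse)
    return CvResult(candidates=grid, mean_mse=mean_mse,
                    best_index=int(np.argmin(mean_mse)), k_folds=k_folds,
                    seed=seed)


@dataclass
class FittedModel:
    """A member of the five-model family, ready for held-out prediction."""

    name: str
    kind: str                     # "svr-rbf" | "svr-linear" | "ols"
    predictor_set: PredictorSet
    hyperparams: SvrHyperparams | None
    cv_mse: float
    _svr: SvrModel | None = None
    _ols: tuple[np.ndarray, float] | None = None   # (slopes, intercept)

    def predict(self, X: np.ndarray, feature_names: tuple[str, ...]) -> np.ndarray:
        """Predict from a full-width feature matrix (columns selected by name)."""
        lookup = {nm: i for i, nm in enumerate(feature_names)}
        try:
            idx = [lookup[m] for m in self.predictor_set.members]
        except KeyError as exc:
            raise StructuralError(f"feature {exc} missing from input") from exc
        Xs = np.asarray(X, dtype=float)[:, idx]
        if self._svr is not None:
            return svr_predict(self._svr, Xs)
        slopes, intercept = self._ols
        return Xs @ slopes + intercept


@dataclass
class ModelFamily:
    models: dict[str, FittedModel]
    sweep: pd.DataFrame


def _ols_fit_cv(X: np.ndarray, y: np.ndarray, k_folds: int, seed: int
                ) -> tuple[np.ndarray, float, float]:
    n = len(y)
    folds = _make_folds(n, min(k_folds, n), seed)
    mses = []
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        A = np.column_stack([X[tr], np.ones(len(tr))])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([X[te], np.ones(len(te))]) @ coef
        mses.append(float(np.mean((y[te] - pred) ** 2)))
    A = np.column_stack([X, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[:-1], float(coef[-1]), float(np.mean(mses))


def fit_model_family(train: ModelingDataset, sets: list[PredictorSet],
                     single_set: PredictorSet, electrode_budget: int = 9,
                     k_folds: int = 10, seed: int = 0,
                     c_grid: tuple[float, ...] = DEFAULT_C_GRID,
                     epsilon_grid: tuple[float, ...] = DEFAULT_EPSILON_GRID,
                     ) -> ModelFamily:
    """Sweep every predictor set with both kernels and assemble Models 1-5.

    For each set and kernel the grid-search CV MSE and winning (C, ε) are
    recorded in the sweep table.  Models 1/3 use each kernel's overall
    best-CV set; Models 2/4 the best among sets within the electrode budget;
    Model 5 is OLS simple regression on the single best predictor.
    """
    if not sets:
        raise ConfigurationError("sets: need at least one predictor set")
    name_to_col = {nm: i for i, nm in enumerate(train.feature_names)}

    rows = []
    cv_by_set: dict[tuple[int, str], CvResult] = {}
    for si, ps in enumerate(sets):
        if ps.n_features == 0:
            continue
        idx = [name_to_col[m] for m in ps.members]
        Xs = train.X[:, idx]
        row = {"threshold": ps.threshold, "n_electrodes": ps.n_electrodes,
               "n_features": ps.n_features}
        for kernel in ("rbf", "linear"):
            cv = grid_search_cv(Xs, train.y, kernel, k_folds=k_folds, seed=seed,
                                c_grid=c_grid, epsilon_grid=epsilon_grid)
            cv_by_set[(si, kernel)] = cv
            row[f"mse_{kernel}"] = cv.best_mse
            row[f"C_{kernel}"] = cv.best.C
            row[f"epsilon_{kernel}"] = cv.best.epsilon
            row[f"gamma"] = cv.best.gamma
        rows.append({"set_index": si, **row})
    sweep = pd.DataFrame(rows)
    if sweep.empty:
        raise ConfigurationError("sets: all candidate sets are empty")

    def _pick(kernel: str, budget: int | None) -> int:
        mask = np.ones(len(sweep), dtype=bool)
        if budget is not None:
            mask = sweep["n_electrodes"].to_numpy() <= budget
            if not mask.any():
                raise ConfigurationError(
                    f"electrode_budget: no predictor set uses <= {budget} electrodes")
        mses = sweep[f"mse_{kernel}"].to_numpy()
        order = np.flatnonzero(mask)
        return int(sweep["set_index"].iloc[order[np.argmin(mses[order])]])

    def _final(name: str, kernel: str, si: int) -> FittedModel:
        ps = sets[si]
        cv = cv_by_set[(si, kernel)]
        idx = [name_to_col[m] for m in ps.members]
        svr = svr_fit(train.X[:, idx], train.y, kernel, cv.best,
                      feature_names=ps.members)
        return FittedModel(name=name, kind=f"svr-{kernel}", predictor_set=ps,
                           hyperparams=cv.best, cv_mse=cv.best_mse, _svr=svr)

    models = {
        "model1": _final("model1", "rbf", _pick("rbf", None)),
        "model3": _final("model3", "linear", _pick("linear", None)),
        "model2": _final("model2", "rbf", _pick("rbf", electrode_budget)),
        "model4": _final("model4", "linear", _pick("linear", electrode_budget)),
    }
    idx5 = [name_to_col[m] for m in single_set.members]
    slopes, intercept, cv_mse5 = _ols_fit_cv(train.X[:, idx5], train.y,
                                             k_folds, seed)
    models["model5"] = FittedModel(name="model5", kind="ols",
                                   predictor_set=single_set, hyperparams=None,
                                   cv_mse=cv_mse5, _ols=(slopes, intercept))
    return ModelFamily(models=models, sweep=sweep)
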