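"""Cross-lagged panel network (CLPN) estimation.

Each wave-2 symptom is regressed on all wave-1 symptoms (L1-penalized)
plus covariates (unpenalized by default) after z-scoring every symptom
column within each wave.  The penalty is selected per outcome by K-fold
cross-validation over a log-spaced grid descending from lambda_max, the
smallest penalty that zeroes all penalized coefficients.  Assembling the
24 nodewise fits column-by-column yields the directed weight matrix W
with autoregressive edges on the diagonal and cross-lagged edges off it.

The nodewise problem is

    min_{beta, gamma}  1/(2n) ||y - X_pen beta - C gamma||^2 + lambda ||beta||_1

with C the intercept plus unpenalized covariate columns.  It is solved by
profiling out gamma (regressing y and X_pen on C and running the lasso on
the residuals — exact by the normal equations for the unpenalized block)
with coordinate descent on the penalized part; every returned fit is
verifiable against the KKT stationarity conditions via
:func:`kkt_residuals`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SymptomCatalog
from .errors import DegenerateColumnError, InputError, ValidationError
from .panel import PanelDataset

# convergence of the coordinate-descent solver
CD_TOL = 1e-7
CD_MAX_ITER = 10_000
#: grid floor as a fraction of lambda_max (glmnet-style for n > p)
LAMBDA_MIN_RATIO = 1e-4
#: stand-in penalty used when lambda = 0 is requested explicitly
_NEAR_ZERO_LAMBDA = 1e-12


@dataclass(frozen=True)
class EstimationConfig:
    """Settings of the nodewise regularized regressions.

    standardize
        z-score every symptom column within each wave (population-sd
        convention, divisor n) before regression.
    cv_folds
        number of cross-validation folds (default 10).
    lambda_rule
        ``"min"`` = CV-error minimizer; ``"one_se"`` = largest lambda
        within one standard error of the minimum.
    lambda_grid_size
        number of grid points, log-spaced down from lambda_max.
    penalize_covariates
        if False (default) covariate columns carry no L1 penalty.
    cv_seed
        seed fixing the fold assignment (same folds for every outcome).
    """

    standardize: bool = True
    cv_folds: int = 10
    lambda_rule: str = "min"
    lambda_grid_size: int = 100
    penalize_covariates: bool = False
    cv_seed: int = 0
    lambda_min_ratio: float = LAMBDA_MIN_RATIO

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValidationError("lambda_rule must be 'min' or 'one_se'")
        if self.lambda_grid_size < 2:
            raise ValidationError("lambda_grid_size must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValidationError("lambda_min_ratio must be in (0, 1)")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_columns(scores: np.ndarray, node_ids: list[str], wave: int | None = None):
    """z-score each column with the population-sd convention (divisor n).

    Returns (standardized matrix, means, sds).  A zero-variance column
    raises :class:`DegenerateColumnError` naming the node.
    """
    scores = np.asarray(scores, dtype=float)
    means = scores.mean(axis=0)
    sds = scores.std(axis=0)  # ddof=0
    for j, sd in enumerate(sds):
        if sd <= 0:
            raise DegenerateColumnError(node_ids[j], wave)
    return (scores - means) / sds, means, sds


def standardize_scores(data: PanelDataset):
    """Standardize both waves of the analysis set.

    Returns ``(z1, z2, records)`` where ``records`` maps wave -> (means,
    sds) for back-mapping to the raw ordinal scale.
    """
    analysis = data.analysis_set()
    ids = data.catalog.node_ids
    z1, m1, s1 = standardize_columns(analysis.scores(1), ids, wave=1)
    z2, m2, s2 = standardize_columns(analysis.scores(2), ids, wave=2)
    return z1, z2, {1: (m1, s1), 2: (m2, s2)}


# ---------------------------------------------------------------------------
# single-outcome L1 regression
# ---------------------------------------------------------------------------

@dataclass
class NodeFit:
    coef: np.ndarray          # full-length coefficient vector (X column order)
    intercept: float
    lambda_selected: float
    lambda_grid: np.ndarray | None = None
    cv_mean_error: np.ndarray | None = None
    cv_se_error: np.ndarray | None = None


def _free_design(X: np.ndarray, free_idx: np.ndarray) -> np.ndarray:
    """Intercept column plus the unpenalized covariate columns."""
    return np.column_stack([np.ones(X.shape[0]), X[:, free_idx]])


def _residualize(C: np.ndarray, M: np.ndarray):
    """Project M on the column space of C; return (residuals, coefs).

    The intercept-only case (no unpenalized covariates) reduces to
    column centering and skips the least-squares solve.
    """
    if C.shape[1] == 1:
        coefs = M.mean(axis=0, keepdims=True)
        return M - coefs, coefs
    coefs, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coefs, coefs


def _cd_path_py(G, g, lambdas, tol, max_iter):
    """Cyclic coordinate descent on the Gram system, warm-started along a
    decreasing penalty grid.  Minimizes 1/(2n)||y - Xb||^2 + lam ||b||_1
    via b_j <- S(g_j - sum_{k!=j} G_jk b_k, lam) / G_jj with
    G = X'X/n, g = X'y/n.  Pure-Python reference used when numba is
    unavailable; semantics identical to the jitted kernel."""
    p = g.shape[0]
    L = lambdas.shape[0]
    out = np.zeros((p, L))
    beta = np.zeros(p)
    for l in range(L):
        lam = lambdas[l]
        for _ in range(max_iter):
            delta = 0.0
            for j in range(p):
                if G[j, j] <= 0.0:
                    continue
                rho = g[j] - G[j] @ beta + G[j, j] * beta[j]
                new = np.sign(rho) * max(abs(rho) - lam, 0.0) / G[j, j]
                d = abs(new - beta[j])
                if d > delta:
                    delta = d
                beta[j] = new
            if delta < tol:
                break
        out[:, l] = beta
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _cd_path_nb(G, g, lambdas, tol, max_iter):  # pragma: no cover
        p = g.shape[0]
        L = lambdas.shape[0]
        out = np.zeros((p, L))
        beta = np.zeros(p)
        for l in range(L):
            lam = lambdas[l]
            for _ in range(max_iter):
                delta = 0.0
                for j in range(p):
                    gjj = G[j, j]
                    if gjj <= 0.0:
                        continue
                    rho = g[j] + gjj * beta[j]
                    for k in range(p):
                        rho -= G[j, k] * beta[k]
                    if rho > lam:
                        new = (rho - lam) / gjj
                    elif rho < -lam:
                        new = (rho + lam) / gjj
                    else:
                        new = 0.0
                    d = abs(new - beta[j])
                    if d > delta:
                        delta = d
                    beta[j] = new
                if delta < tol:
                    break
            out[:, l] = beta
        return out

    _cd_path = _cd_path_nb
except ImportError:  # pragma: no cover
    _cd_path = _cd_path_py


def _lasso_solve(Xr: np.ndarray, yr: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Penalized coefficients along a decreasing lambda grid.

    ``Xr``/``yr`` must already be orthogonal to the unpenalized block.
    Returns an array of shape (p_penalized, len(lambdas)).
    """
    n = Xr.shape[0]
    G = (Xr.T @ Xr) / n
    g = (Xr.T @ yr) / n
    alphas = np.maximum(np.asarray(lambdas, dtype=float), _NEAR_ZERO_LAMBDA)
    return _cd_path(G, g, alphas, CD_TOL, CD_MAX_ITER)


def lambda_grid(Xr: np.ndarray, yr: np.ndarray, size: int, min_ratio: float) -> np.ndarray:
    """Log-spaced strictly decreasing grid starting at lambda_max, the
    smallest penalty at which every penalized coefficient is zero."""
    n = Xr.shape[0]
    lam_max = float(np.max(np.abs(Xr.T @ yr)) / n)
    if lam_max <= 0:
        lam_max = 1e-6  # outcome orthogonal to all predictors
    return lam_max * np.logspace(0.0, np.log10(min_ratio), size)


@lru_cache(maxsize=64)
def _fold_ids(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ids = np.resize(np.arange(k), n)
    return rng.permutation(ids)


def fit_node_regression(
    y: np.ndarray,
    X: np.ndarray,
    penalty_free: tuple[int, ...] = (),
    config: EstimationConfig | None = None,
    lambda_override: float | None = None,
) -> NodeFit:
    """L1-penalized regression of one outcome with CV penalty selection.

    ``penalty_free`` lists columns of X exempt from the penalty (ignored
    when ``config.penalize_covariates``).  ``lambda_override`` skips CV
    and fits at the given penalty (0 = ordinary least squares limit).
    """
    config = config or EstimationConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise InputError("X and y have different numbers of rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in regression inputs")
    if lambda_override is None and n <= config.cv_folds:
        raise InputError(
            f"need more rows ({n}) than CV folds ({config.cv_folds})"
        )

    free = np.array(sorted(set(penalty_free)), dtype=int) if not config.penalize_covariates else np.array([], dtype=int)
    pen = np.array([j for j in range(p) if j not in set(free.tolist())], dtype=int)
    C = _free_design(X, free)
    Xp = X[:, pen]

    (resid, _) = _residualize(C, np.column_stack([y, Xp]))
    yr, Xr = resid[:, 0], resid[:, 1:]

    grid = None
    cv_mean = cv_se = None
    if lambda_override is not None:
        if lambda_override < 0:
            raise InputError("lambda_override must be >= 0")
        lam = float(lambda_override)
    else:
        grid = lambda_grid(Xr, yr, config.lambda_grid_size, config.lambda_min_ratio)
        folds = _fold_ids(n, config.cv_folds, config.cv_seed)
        errs = np.empty((config.cv_folds, grid.size))
        for k in range(config.cv_folds):
            tr, va = folds != k, folds == k
            rt, _ = _residualize(C[tr], np.column_stack([y[tr], Xp[tr]]))
            betas = _lasso_solve(rt[:, 1:], rt[:, 0], grid)
            # unpenalized block refit jointly with each beta on the fold
            _, gam = _residualize(C[tr], y[tr, None] - Xp[tr] @ betas)
            pred = Xp[va] @ betas + C[va] @ gam
            errs[k] = ((y[va, None] - pred) ** 2).mean(axis=0)
        cv_mean = errs.mean(axis=0)
        cv_se = errs.std(axis=0, ddof=1) / np.sqrt(config.cv_folds)
        i_min = int(np.argmin(cv_mean))
        if config.lambda_rule == "min":
            lam = float(grid[i_min])
        else:  # one_se: largest lambda within one SE of the minimum
            ok = cv_mean <= cv_mean[i_min] + cv_se[i_min]
            lam = float(grid[np.flatnonzero(ok)[0]])

    beta = _lasso_solve(Xr, yr, np.array([lam]))[:, 0]
    _, gamma = _residualize(C, (y - Xp @ beta)[:, None])
    gamma = gamma[:, 0]

    coef = np.zeros(p)
    coef[pen] = beta
    if free.size:
        coef[free] = gamma[1:]
    return NodeFit(
        coef=coef,
        intercept=float(gamma[0]),
        lambda_selected=lam,
        lambda_grid=grid,
        cv_mean_error=cv_mean,
        cv_se_error=cv_se,
    )


def kkt_residuals(
    y: np.ndarray,
    X: np.ndarray,
    fit: NodeFit,
    penalty_free: tuple[int, ...] = (),
) -> dict[str, float]:
    """Stationarity (KKT) residuals of a returned fit.

    For the L1 problem the gradient g = X'(y - X coef - b0)/n must satisfy
    g_j = lambda * sign(coef_j) on active penalized coordinates,
    |g_j| <= lambda on zeroed ones, and g_j = 0 on unpenalized
    coordinates (and for the intercept).  Returns the maximal violation
    of each condition.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = len(y)
    r = y - X @ fit.coef - fit.intercept
    g = X.T @ r / n
    lam = fit.lambda_selected
    free = set(penalty_free)
    zero_viol = active_viol = free_viol = 0.0
    for j in range(X.shape[1]):
        if j in free:
            free_viol = max(free_viol, abs(g[j]))
        elif fit.coef[j] == 0.0:
            zero_viol = max(zero_viol, max(abs(g[j]) - lam, 0.0))
        else:
            active_viol = max(active_viol, abs(g[j] - lam * np.sign(fit.coef[j])))
    return {
        "zero": zero_viol,
        "active": active_viol,
        "free": max(free_viol, abs(r.mean())),
    }


# ---------------------------------------------------------------------------
# full-network fit
# ---------------------------------------------------------------------------

@dataclass
class CrossLaggedNetwork:
    """Directed cross-lagged network over a symptom catalog.

    ``W[i, j]`` is the standardized coefficient of T1 node i predicting
    T2 node j; the diagonal holds the autoregressive edges.
    """

    W: np.ndarray
    covariate_coefs: pd.DataFrame  # outcomes x covariates
    intercepts: np.ndarray
    lambda_selected: np.ndarray
    config: EstimationConfig
    catalog: SymptomCatalog
    n_subjects: int

    @property
    def n_nodes(self) -> int:
        return len(self.catalog)

    def weight(self, src: str, dst: str) -> float:
        return float(self.W[self.catalog.index(src), self.catalog.index(dst)])

    # -- exports -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "catalog": self.catalog.to_records(),
            "W": self.W.tolist(),
            "covariate_coefs": {
                c: self.covariate_coefs[c].tolist() for c in self.covariate_coefs
            },
            "intercepts": self.intercepts.tolist(),
            "lambda_selected": self.lambda_selected.tolist(),
            "config": vars(self.config),
            "n_subjects": self.n_subjects,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "CrossLaggedNetwork":
        catalog = SymptomCatalog.from_records(d["catalog"])
        return cls(
            W=np.asarray(d["W"], dtype=float),
            covariate_coefs=pd.DataFrame(
                d["covariate_coefs"], index=catalog.node_ids
            ),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            lambda_selected=np.asarray(d["lambda_selected"], dtype=float),
            config=EstimationConfig(**d["config"]),
            catalog=catalog,
            n_subjects=int(d["n_subjects"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CrossLaggedNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def edge_list(self) -> pd.DataFrame:
        """All n^2 directed edges: from, to, weight, edge_type."""
        ids = self.catalog.node_ids
        rows = []
        for i, src in enumerate(ids):
            for j, dst in enumerate(ids):
                rows.append(
                    {
                        "from": src,
                        "to": dst,
                        "weight": float(self.W[i, j]),
                        "edge_type": "auto" if i == j else "cross",
                    }
                )
        return pd.DataFrame(rows)


def fit_network_matrices(
    t1: np.ndarray,
    t2: np.ndarray,
    catalog: SymptomCatalog,
    covariates: pd.DataFrame | None = None,
    config: EstimationConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> CrossLaggedNetwork:
    """Fit the CLPN from raw score matrices (array-level entry point).

    ``covariates`` columns enter every nodewise regression unpenalized
    (unless ``config.penalize_covariates``).  ``lambdas`` fixes the
    per-outcome penalty and skips CV (used by the fast bootstrap mode).
    """
    config = config or EstimationConfig()
    ids = catalog.node_ids
    p = len(ids)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape or t1.shape[1] != p:
        raise InputError("t1/t2 must be n_subjects x n_nodes matrices")
    n = t1.shape[0]
    if n == 0:
        raise InputError("empty analysis set")

    if config.standardize:
        z1, _, _ = standardize_columns(t1, ids, wave=1)
        z2, _, _ = standardize_columns(t2, ids, wave=2)
    else:
        z1, z2 = t1, t2

    cov_names: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        cov_names = list(covariates.columns)
        X = np.column_stack([z1, covariates.to_numpy(dtype=float)])
    else:
        X = z1
    penalty_free = tuple(range(p, p + len(cov_names)))

    W = np.zeros((p, p))
    cov_coefs = np.zeros((p, len(cov_names)))
    intercepts = np.zeros(p)
    lam_sel = np.zeros(p)
    for j in range(p):
        fit = fit_node_regression(
            z2[:, j],
            X,
            penalty_free=penalty_free,
            config=config,
            lambda_override=None if lambdas is None else float(lambdas[j]),
        )
        W[:, j] = fit.coef[:p]
        if cov_names:
            cov_coefs[j] = fit.coef[p:]
        intercepts[j] = fit.intercept
        lam_sel[j] = fit.lambda_selected
    return CrossLaggedNetwork(
        W=W,
        covariate_coefs=pd.DataFrame(cov_coefs, index=ids, columns=cov_names),
        intercepts=intercepts,
        lambda_selected=lam_sel,
        config=config,
        catalog=catalog,
        n_subjects=n,
    )


def fit_clpn(
    data: PanelDataset,
    config: EstimationConfig | None = None,
    group_filter: int | None = None,
    lambdas: np.ndarray | None = None,
) -> CrossLaggedNetwork:
    """Fit the CLPN from a panel dataset.

    The whole-sample network adjusts for gender as an unpenalized
    covariate; when ``group_filter`` (a gender code) is given, the fit
    uses that subset and omits the now-constant covariate.
    """
    config = config or EstimationConfig()
    if group_filter is None:
        analysis = data.analysis_set()
        covs = pd.DataFrame({"gender": analysis.gender.astype(float)})
    else:
        analysis = data.subset_by_gender(group_filter)
        covs = None
    if analysis.n_subjects == 0:
        raise InputError("analysis set is empty after filtering")
    return fit_network_matrices(
        analysis.scores(1),
        analysis.scores(2),
        data.catalog,
        covariates=covs,
        config=config,
        lambdas=lambdas,
    )


@dataclass(frozen=True)
class EdgeSummary:
    mean_abs_auto: float
    mean_abs_cross: float
    n_cross_edges: int
    n_nonzero_cross: int


def edge_summary(net: CrossLaggedNetwork) -> EdgeSummary:
    """Mean absolute autoregressive vs cross-lagged edge strength."""
    W = net.W
    p = W.shape[0]
    off = ~np.eye(p, dtype=bool)
    return EdgeSummary(
        mean_abs_auto=float(np.abs(np.diag(W)).mean()),
        mean_abs_cross=float(np.abs(W[off]).mean()),
        n_cross_edges=p * p - p,
        n_nonzero_cross=int(np.count_nonzero(W[off])),
    )
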