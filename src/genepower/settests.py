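"""Single-marker trend test and the five gene-based SNP-set tests.

Methods
-------
GATES
    Simes-type combination of per-SNP trend-test p-values, rescaled by the
    effective number of independent tests Me derived from the eigenvalues of
    the p-value correlation matrix:  P = min_j  Me * p_(j) / Me(j).
VEGAS-SUM / VEGAS-MAX
    Sum (or max) of the per-SNP 1-df trend chi-squares, referred to a Monte
    Carlo null built by squaring correlated standard normals (Cholesky factor
    of the sample LD matrix).
LR
    Likelihood-ratio test of a logistic model with one additive covariate per
    SNP against the intercept-only model.
LR-PC
    Same, but on the minimal set of principal components of the standardized
    genotype matrix explaining >= 80% of the genotype correlation.

All tests drop monomorphic columns first (an empty set yields p = 1) and are
invariant to SNP column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from ._rng import as_generator
from .errors import NumericalError, ParameterError
from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeVector

__all__ = [
    "SingleMarkerResult",
    "LDMatrix",
    "SetTestResult",
    "trend_test",
    "trend_statistics",
    "pairwise_ld",
    "gates",
    "gates_pvalue_correlation",
    "vegas",
    "lr_test",
    "lr_pc_test",
    "METHODS",
]

METHODS = ("GATES", "VEGAS-SUM", "VEGAS-MAX", "LR-PC", "LR")


@dataclass
class SingleMarkerResult:
    snp_id: str
    statistic: float
    p_value: float


@dataclass
class LDMatrix:
    """Pairwise Pearson correlation of additive genotype codes."""

    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ParameterError("LD matrix must be square")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2


@dataclass
class SetTestResult:
    method: str
    p_value: float
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Single-marker trend test
# ---------------------------------------------------------------------------

def trend_statistics(values: np.ndarray, status: np.ndarray):
    """Vectorized Cochran-Armitage trend chi-squares for every column.

    The additive-score trend statistic in its score-test form equals
    n * corr(G, D)^2; monomorphic columns get statistic 0, p = 1.
    Returns (statistics, p_values).
    """
    y = np.asarray(status, dtype=float)
    n = y.shape[0]
    if y.sum() in (0, n):
        raise ParameterError("need both cases and controls for the trend test")
    G = np.asarray(values, dtype=float)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    gss = (Gc**2).sum(axis=0)
    yss = (yc**2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Gc.T @ yc) / np.sqrt(gss * yss)
    rho = np.where(gss > 0, rho, 0.0)
    statistic = n * rho**2
    return statistic, stats.chi2.sf(statistic, df=1)


def trend_test(genotype_column, status: PhenotypeVector,
               snp_id: str = "snp") -> SingleMarkerResult:
    """Cochran-Armitage additive trend test for a single SNP."""
    col = np.asarray(genotype_column).reshape(-1, 1)
    stat, p = trend_statistics(col, status.status)
    return SingleMarkerResult(snp_id, float(stat[0]), float(p[0]))


def pairwise_ld(genotypes: GenotypeMatrix | np.ndarray) -> LDMatrix:
    """Sample LD matrix (Pearson r of genotype codes).

    Monomorphic columns are assigned zero correlation with everything else
    (unit diagonal) rather than NaN.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ParameterError("need at least 2 individuals to estimate LD")
    sd = values.std(axis=0)
    poly = sd > 0
    r = np.zeros((values.shape[1], values.shape[1]))
    if poly.any():
        sub = np.corrcoef(values[:, poly], rowvar=False)
        sub = np.atleast_2d(sub)
        r[np.ix_(poly, poly)] = sub
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r)


# ---------------------------------------------------------------------------
# GATES
# ---------------------------------------------------------------------------

_GATES_POLY = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)


def gates_pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Approximate correlation of trend-test p-values from genotype LD ``r``.

    Sixth-order polynomial fit from the GATES literature, evaluated at |r|;
    a simpler fallback (rho = r**2) can be passed to :func:`gates` instead.
    """
    rho = np.polyval(_GATES_POLY, np.abs(r))
    rho = np.clip(rho, 0.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _effective_tests(rho: np.ndarray) -> float:
    """Me = M - sum_{lambda_i > 1} (lambda_i - 1)."""
    lam = np.linalg.eigvalsh(rho)
    return rho.shape[0] - float(np.clip(lam - 1.0, 0.0, None).sum())


def gates(p_values, ld: LDMatrix, transform=gates_pvalue_correlation) -> SetTestResult:
    """Extended-Simes set p-value:  min_j  Me * p_(j) / Me(j)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = p.shape[0]
    if ld.r.shape[0] != m:
        raise ParameterError("p-value vector and LD matrix dimensions differ")
    if m == 0:
        return SetTestResult("GATES", 1.0, {"me": 0.0, "me_j": []})
    order = np.argsort(p)
    rho = transform(ld.r)[np.ix_(order, order)]
    me = _effective_tests(rho)
    me_j = np.array([_effective_tests(rho[:j, :j]) for j in range(1, m + 1)])
    candidates = me * p[order] / me_j
    return SetTestResult("GATES", float(min(candidates.min(), 1.0)),
                         {"me": me, "me_j": me_j})


# ---------------------------------------------------------------------------
# VEGAS
# ---------------------------------------------------------------------------

_JITTER_START, _JITTER_MAX = 1e-8, 1e-4


def _regularized_cholesky(r: np.ndarray) -> np.ndarray:
    jitter = 0.0
    while True:
        try:
            return np.linalg.cholesky(r + jitter * np.eye(r.shape[0]))
        except np.linalg.LinAlgError:
            jitter = _JITTER_START if jitter == 0.0 else jitter * 10
            if jitter > _JITTER_MAX:
                cond = np.linalg.cond(r)
                raise NumericalError(
                    f"LD matrix not positive definite even with jitter "
                    f"{_JITTER_MAX:g} (condition number {cond:.3g})"
                ) from None


def _vegas_null_chi2(ld: LDMatrix, n_sim: int, rng) -> np.ndarray:
    """(n_sim, M) matrix of squared correlated standard normals."""
    chol = _regularized_cholesky(ld.r)
    z = rng.standard_normal((n_sim, ld.r.shape[0])) @ chol.T
    return z**2


def vegas(statistics, ld: LDMatrix, mode: str = "sum", n_sim: int = 1000,
          seed=None, null_chi2: np.ndarray | None = None) -> SetTestResult:
    """Monte Carlo set test on the per-SNP trend chi-squares.

    ``null_chi2`` lets callers share one matrix of simulated squared normals
    between the sum and max statistics.  Exceedance is counted non-strictly
    and the p-value uses the (1 + k) / (1 + n_sim) correction so p > 0.
    """
    if mode not in ("sum", "max"):
        raise ParameterError("mode must be 'sum' or 'max'")
    stat = np.atleast_1d(np.asarray(statistics, dtype=float))
    if ld.r.shape[0] != stat.shape[0]:
        raise ParameterError("statistic vector and LD matrix dimensions differ")
    if stat.shape[0] == 0:
        return SetTestResult(f"VEGAS-{mode.upper()}", 1.0, {"n_sim": 0, "exceed": 0})
    if null_chi2 is None:
        if n_sim < 100:
            raise ParameterError("n_sim must be at least 100")
        null_chi2 = _vegas_null_chi2(ld, n_sim, as_generator(seed))
    n_sim = null_chi2.shape[0]
    if mode == "sum":
        observed = stat.sum()
        null = null_chi2.sum(axis=1)
    else:
        observed = stat.max()
        null = null_chi2.max(axis=1)
    exceed = int((null >= observed).sum())
    return SetTestResult(f"VEGAS-{mode.upper()}", (1 + exceed) / (1 + n_sim),
                         {"n_sim": n_sim, "exceed": exceed, "observed": observed})


# ---------------------------------------------------------------------------
# Logistic-regression tests
# ---------------------------------------------------------------------------

def _polymorphic_columns(values: np.ndarray) -> np.ndarray:
    return np.flatnonzero(values.std(axis=0) > 0)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _logit_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
               tol: float = 1e-10):
    """Newton-Raphson logistic fit with step halving.

    Returns (loglik, converged).  The design is assumed full rank; quasi-
    separated fits are reported as non-converged.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll = _logit_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return ll, False
        # step halving keeps the likelihood monotone
        factor = 1.0
        for _ in range(30):
            ll_new = _logit_loglik(X, y, beta + factor * step)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        if ll_new - ll < tol * (abs(ll) + 1.0):
            return ll_new, True
        ll = ll_new
    return ll, False


def _null_loglik(y: np.ndarray) -> float:
    n = y.shape[0]
    k = y.sum()
    if k in (0, n):
        raise ParameterError("need both cases and controls")
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def _lrt(X: np.ndarray, y: np.ndarray, method: str, extra=None) -> SetTestResult:
    df = X.shape[1]
    details = {"df": df, "converged": True}
    if extra:
        details.update(extra)
    if df == 0:
        return SetTestResult(method, 1.0, details)
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    ll1, converged = _fit_logit(Xc, y)
    ll0 = _null_loglik(y)
    stat = max(2.0 * (ll1 - ll0), 0.0)
    details.update({"statistic": stat, "converged": converged})
    return SetTestResult(method, float(stats.chi2.sf(stat, df)), details)


def lr_test(genotypes: GenotypeMatrix | np.ndarray,
            status: PhenotypeVector | np.ndarray) -> SetTestResult:
    """Logistic LRT with one additive covariate per (retained) SNP.

    Monomorphic and linearly dependent columns are dropped before fitting;
    the chi-square df equals the retained column count.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    y = status.status if isinstance(status, PhenotypeVector) else np.asarray(status)
    y = y.astype(float)
    X = np.asarray(values, dtype=float)
    keep = _polymorphic_columns(X)
    X = X[:, keep]
    Xc = X - X.mean(axis=0)  # centering stabilizes the Newton steps
    indep = _independent_columns(Xc)
    return _lrt(Xc[:, indep], y, "LR", {"n_dropped": values.shape[1] - indep.size})


def lr_pc_test(genotypes: GenotypeMatrix | np.ndarray,
               status: PhenotypeVector | np.ndarray,
               variance_threshold: float = 0.80) -> SetTestResult:
    """Logistic LRT on the leading principal components of the genotypes.

    Columns are standardized (correlation-matrix PCA); the minimal number of
    components X with cumulative explained variance >= ``variance_threshold``
    is retained and reported in the details.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    y = status.status if isinstance(status, PhenotypeVector) else np.asarray(status)
    y = y.astype(float)
    X = np.asarray(values, dtype=float)
    keep = _polymorphic_columns(X)
    X = X[:, keep]
    if X.shape[1] == 0:
        return SetTestResult("LR-PC", 1.0, {"df": 0, "n_components": 0,
                                            "converged": True})
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    explained = s**2 / (s**2).sum()
    n_comp = int(np.searchsorted(np.cumsum(explained), variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, s.size)
    scores = U[:, :n_comp] * s[:n_comp]
    result = _lrt(scores, y, "LR-PC", {"n_components": n_comp,
                                       "explained": explained[:n_comp].sum()})
    return result
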