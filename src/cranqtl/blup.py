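"""Genomic-relationship mixed models: REML variance components, BLUPs, h².

Within-year model:   y = mu        + Zg g + Zr r + Zc c + Zs s + e
Across-year model:   y = mu + Xe e + Zg g + Zge ge + Zr r + Zc c + Zs s + e

with g ~ N(0, A·sigma_a²) for a genomic relationship matrix A, all other
random terms iid, and e ~ N(0, I·sigma_e²). Variance components are
estimated by restricted maximum likelihood (dense likelihood, analytic
gradient, non-negativity enforced by box constraints); the genotype BLUPs
(GEBVs) come from the mixed-model equations at the optimum. Random-term
structure is chosen by AIC over all subsets of {row, column, spline}, and
the genotype-by-year term is retained only if a boundary-corrected
likelihood-ratio test (½χ²₀+½χ²₁ mixture) is significant.

Narrow-sense genomic heritability:
    within-year  h² = sigma_a² / (sigma_a² + sigma_e²)
    across-year  h² = sigma_a² / (sigma_a² + sigma_ge²/n + sigma_e²/n)
for n the number of years fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


def compute_A(dosages: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """VanRaden method-1 additive genomic relationship matrix from 0/1/2 dosages.

    ``A = W W' / (2 Σ p_k (1-p_k))`` with W the column-centered dosage matrix
    and p_k the observed allele frequency of marker k. Monomorphic markers
    carry no relationship information and are dropped with a warning.
    """
    if isinstance(dosages, pd.DataFrame):
        ids = dosages.index
        M = dosages.to_numpy(dtype=float)
    else:
        M = np.asarray(dosages, dtype=float)
        ids = pd.RangeIndex(M.shape[0])
    if M.shape[0] < 2 or M.shape[1] < 10:
        raise ValueError("need >= 2 genotypes and >= 10 markers")
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (M.var(axis=0) > 0)
    if not poly.any():
        raise ValueError("all markers monomorphic")
    if (~poly).any():
        warnings.warn(f"dropping {(~poly).sum()} monomorphic markers")
    M, p = M[:, poly], p[poly]
    W = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    A = W @ W.T / denom
    return pd.DataFrame(A, index=ids, columns=ids)


@dataclass
class RandomTerm:
    """One random effect u ~ N(0, K·sigma²) entering the model as Z u (K=None ⇒ I)."""

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None
    levels: list = field(default_factory=list)

    def vmat(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class VarianceComponents:
    components: dict[str, float]
    residual: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return self.residual if name == "residual" else self.components[name]


@dataclass
class BlupResult:
    effects: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    levels: dict[str, list]
    beta: np.ndarray

    def genotype_blups(self, term: str = "genotype") -> pd.Series:
        return pd.Series(self.effects[term], index=self.levels[term], name="blup")


def _nll_dense(theta, y, X, vmats):
    """-2x restricted log-likelihood (up to constant) and its gradient, dense V."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, Vk in zip(theta[:-1], vmats):
        V += t * Vk
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    Py = Vi @ y - ViX @ beta
    yPy = float(y @ Py)
    nll = logdetV + logdetX + yPy

    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    grad = np.empty_like(theta)
    for k, Vk in enumerate(vmats):
        # both symmetric, so tr(P Vk) is an elementwise sum
        grad[k] = np.sum(P * Vk) - Py @ Vk @ Py
    grad[-1] = np.trace(P) - Py @ Py
    return nll, grad


def _nll_diag(theta, ytil, Xtil, d):
    """Same likelihood for the single-random-term model after eigenrotation.

    V = theta_1 * diag(d) + theta_e * I is diagonal in the rotated basis, so
    every evaluation is O(n p²) instead of O(n³).
    """
    v = theta[0] * d + theta[1]
    if np.any(v <= 0):
        return np.inf, np.zeros_like(theta)
    w = 1.0 / v
    Xw = Xtil * w[:, None]
    XtWX = Xtil.T @ Xw
    sign, logdetX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    beta = np.linalg.solve(XtWX, Xw.T @ ytil)
    Py = w * (ytil - Xtil @ beta)
    nll = np.log(v).sum() + logdetX + float(ytil @ Py)

    grad = np.empty(2)
    B = np.linalg.solve(XtWX, Xw.T)          # p x n, equals (X'WX)^-1 X'W
    for k, m in enumerate((d, np.ones_like(d))):
        trPM = float(np.sum(w * m)) - float(np.einsum("pn,n,np->", B, m * w, Xtil))
        grad[k] = trPM - float(np.sum(m * Py * Py))
    return nll, grad


def fit_reml(y: np.ndarray, X: np.ndarray, terms: list[RandomTerm],
             max_iter: int = 200, tol: float = 1e-12
             ) -> tuple[VarianceComponents, BlupResult]:
    """REML fit of a Gaussian mixed model; returns variance components and BLUPs.

    Non-negativity is enforced by bounding each variance at zero (residual
    at a small positive floor). Non-convergence is flagged on the result,
    never raised silently.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X disagree on n")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    vary = float(np.var(y))
    k = len(terms)
    n_params = p + k + 1

    if vary == 0.0:
        vc = VarianceComponents({t.name: 0.0 for t in terms}, 0.0, 0.0,
                                2.0 * n_params, n_params, True, 0)
        blup = BlupResult({t.name: np.zeros(t.Z.shape[1]) for t in terms},
                          {t.name: np.zeros(t.Z.shape[1]) for t in terms},
                          {t.name: t.levels for t in terms},
                          np.linalg.lstsq(X, y, rcond=None)[0])
        return vc, blup

    # standardize the response so variances are optimized in units of var(y);
    # this keeps the problem well conditioned for traits of any scale
    s = np.sqrt(vary)
    ys = y / s
    theta0 = np.full(k + 1, 1.0 / (k + 1))
    bounds = [(0.0, None)] * k + [(1e-10, None)]

    if k == 1:
        # rotate into the eigenbasis of the single relationship structure
        V1 = terms[0].vmat()
        d, U = np.linalg.eigh(V1)
        d = np.clip(d, 0.0, None)
        ytil, Xtil = U.T @ ys, U.T @ X
        fun = lambda th: _nll_diag(th, ytil, Xtil, d)
    else:
        vmats = [t.vmat() for t in terms]
        fun = lambda th: _nll_dense(th, ys, X, vmats)

    res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-9})
    theta_s = np.clip(res.x, 0.0, None)
    nll_s, grad_s = fun(theta_s)
    converged = bool(res.success) or float(np.abs(grad_s).max()) < 1e-4
    theta = theta_s * vary
    # restricted log-likelihood back on the original response scale
    loglik = -0.5 * float(nll_s) - (n - p) * np.log(s)
    aic = -2.0 * loglik + 2.0 * n_params
    vc = VarianceComponents({t.name: float(v) for t, v in zip(terms, theta[:-1])},
                            float(theta[-1]), float(loglik), float(aic),
                            n_params, converged, int(res.nit))

    # BLUPs at the optimum from the dense representation
    V = theta[-1] * np.eye(n)
    for t, Vk in zip(theta[:-1], [t.vmat() for t in terms]):
        V += t * Vk
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    effects, ses, levels = {}, {}, {}
    for t, s2 in zip(terms, theta[:-1]):
        KZt = t.Z.T if t.K is None else t.K @ t.Z.T
        u = s2 * KZt @ Py
        G = s2 * (np.eye(t.Z.shape[1]) if t.K is None else t.K)
        pev = np.clip(np.diag(G) - np.diag(s2 * KZt @ P @ KZt.T * s2), 0.0, None)
        effects[t.name] = u
        ses[t.name] = np.sqrt(pev)
        levels[t.name] = t.levels
    return vc, BlupResult(effects, ses, levels, beta)


# ---------------------------------------------------------------------------
# design construction

def incidence(values, levels=None) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix of a factor, with its level ordering."""
    values = pd.Series(values)
    if levels is None:
        levels = sorted(values.unique())
    idx = values.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), idx] = 1.0
    return Z, list(levels)


def spline_basis(row: np.ndarray, col: np.ndarray,
                 n_knots: tuple[int, int] = (6, 6)) -> np.ndarray:
    """Tensor-product cubic B-spline basis over field (row, column) coordinates.

    Models smooth spatial variation that neither straight-line trends nor
    row/column blocking capture. The coefficient vector gets an iid variance,
    so basis dimension (default 6x6) controls smoothness.
    """
    from scipy.interpolate import BSpline

    def marginal(x, m):
        x = np.asarray(x, dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            hi = lo + 1.0
        deg = 3
        n_inner = max(m - deg - 1, 0)
        inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
        t = np.concatenate([[lo] * (deg + 1), inner, [hi] * (deg + 1)])
        return BSpline.design_matrix(np.clip(x, lo, hi), t, deg).toarray()

    Br = marginal(row, n_knots[0])
    Bc = marginal(col, n_knots[1])
    # row-wise Kronecker product
    return np.einsum("ni,nj->nij", Br, Bc).reshape(len(Br), -1)


def build_terms(data: pd.DataFrame, A: pd.DataFrame | None = None,
                include: tuple[str, ...] = ("row", "col", "spline"),
                gxy: bool = False,
                spline_knots: tuple[int, int] = (6, 6)) -> list[RandomTerm]:
    """Random terms for the field mixed models from a tidy phenotype table.

    The genotype term is always present (with covariance A when supplied);
    ``include`` selects spatial terms from {"row", "col", "spline"}; ``gxy``
    adds the genotype-by-year interaction (across-year model only).
    """
    terms = []
    if A is not None:
        levels = [g for g in A.index if g in set(data["genotype"])]
        Zg, levels = incidence(data["genotype"], levels)
        K = A.loc[levels, levels].to_numpy()
    else:
        Zg, levels = incidence(data["genotype"])
        K = None
    terms.append(RandomTerm("genotype", Zg, K, levels))
    if gxy:
        combo = data["genotype"].astype(str) + ":" + data["year"].astype(str)
        Zge, lev = incidence(combo)
        terms.append(RandomTerm("gxy", Zge, None, lev))
    if "row" in include:
        Zr, lev = incidence(data["row"])
        terms.append(RandomTerm("row", Zr, None, lev))
    if "col" in include:
        Zc, lev = incidence(data["col"])
        terms.append(RandomTerm("col", Zc, None, lev))
    if "spline" in include:
        Zs = spline_basis(data["row"].to_numpy(), data["col"].to_numpy(),
                          spline_knots)
        terms.append(RandomTerm("spline", Zs, None,
                                [f"s{i}" for i in range(Zs.shape[1])]))
    return terms


def fixed_design(data: pd.DataFrame, year_fixed: bool = False
                 ) -> tuple[np.ndarray, list]:
    """Intercept, plus treatment-coded year effects for the across-year model."""
    n = len(data)
    if not year_fixed:
        return np.ones((n, 1)), ["intercept"]
    years = sorted(data["year"].unique())
    X = np.ones((n, len(years)))
    names = ["intercept"]
    for j, yr in enumerate(years[1:], start=1):
        X[:, j] = (data["year"] == yr).to_numpy(dtype=float)
        names.append(f"year[{yr}]")
    return X, names


def select_model_aic(y: np.ndarray, X: np.ndarray, data: pd.DataFrame,
                     A: pd.DataFrame | None = None, gxy: bool = False,
                     optional: tuple[str, ...] = ("row", "col", "spline"),
                     spline_knots: tuple[int, int] = (6, 6),
                     **fit_kw):
    """Full AIC search over subsets of the optional spatial random terms.

    The genotype term (and GxY when requested) is forced into every
    candidate. Ties are broken toward the smaller model; all-candidate
    non-convergence raises.
    """
    results = []
    for r in range(len(optional) + 1):
        for subset in itertools.combinations(optional, r):
            terms = build_terms(data, A=A, include=subset, gxy=gxy,
                                spline_knots=spline_knots)
            try:
                vc, blup = fit_reml(y, X, terms, **fit_kw)
            except Exception:
                continue
            results.append((subset, vc, blup, terms))
    converged = [r for r in results if r[1].converged]
    if not converged:
        raise RuntimeError("no candidate model converged")
    # sorted by subset size first, so argmin on AIC keeps the smaller model on ties
    best = min(converged, key=lambda r: (r[1].aic, len(r[0])))
    table = pd.DataFrame([{"terms": "+".join(r[0]) or "(none)", "aic": r[1].aic,
                           "loglik": r[1].loglik, "converged": r[1].converged}
                          for r in results])
    return best[0], best[1], best[2], best[3], table


def gate_gxy(vc_with: VarianceComponents, vc_without: VarianceComponents,
             alpha: float = 0.05) -> tuple[bool, float, float]:
    """Boundary-corrected LRT for the genotype-by-year variance.

    The null value sits on the boundary of the parameter space, so the LRT
    statistic is referenced to the ½χ²₀ + ½χ²₁ mixture. Returns
    ``(keep_ge, statistic, p_value)``.
    """
    if vc_with.n_params != vc_without.n_params + 1:
        raise ValueError("fits are not nested with one extra variance")
    stat = 2.0 * (vc_with.loglik - vc_without.loglik)
    if stat <= 0:
        return False, max(stat, 0.0), 1.0
    p = 0.5 * stats.chi2.sf(stat, df=1)
    return p < alpha, float(stat), float(p)


def heritability(vc: VarianceComponents, across_year: bool = False,
                 n_years: int | None = None) -> float:
    """Narrow-sense genomic heritability from fitted variance components.

    Within-year: sigma_a²/(sigma_a²+sigma_e²). Across years the GxY and
    residual variances are divided by the number of years, reflecting the
    averaging of year replicates in the genotype means the BLUPs represent.
    Returns NaN when the denominator is zero (undefined).
    """
    sa = vc.components.get("genotype", 0.0)
    se = vc.residual
    if not across_year:
        denom = sa + se
    else:
        if n_years is None or n_years < 1:
            raise ValueError("across-year heritability needs n_years >= 1")
        sge = vc.components.get("gxy", 0.0)
        denom = sa + sge / n_years + se / n_years
    if denom == 0:
        return float("nan")
    return float(sa / denom)
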