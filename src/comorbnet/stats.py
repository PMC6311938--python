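"""Shared statistical primitives.

One-sided / two-sided Fisher exact tests on 2x2 tables, Benjamini-Hochberg
false-discovery-rate adjustment, and a maximum-likelihood logistic fitter
with explicit convergence / separation diagnostics.  Everything downstream
(eQTL-RNA overlap enrichment, directional comorbidity models, the final
concordance test) is built on these three operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Contingency2x2",
    "TestResult",
    "LogisticFit",
    "fisher_exact_2x2",
    "bh_adjust",
    "fit_logistic",
    "irls_logistic",
]

#: absolute coefficient magnitude beyond which a logistic fit is flagged
#: as (quasi-)separated rather than trusted
SEPARATION_BETA = 20.0


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 contingency table; ``a`` is the in-both cell.

    Layout::

                 condition2+   condition2-
        cond1+       a             b
        cond1-       c             d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """Sample odds ratio ad/bc.

        Conventions: ``bc == 0`` with ``ad > 0`` gives ``inf``; ``ad == 0``
        with ``bc > 0`` gives ``0``; both zero gives ``nan``.
        """
        ad = self.a * self.d
        bc = self.b * self.c
        if bc == 0:
            return float("nan") if ad == 0 else float("inf")
        return ad / bc


@dataclass(frozen=True)
class TestResult:
    odds_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_2x2(
    table: Contingency2x2,
    alternative: str = "greater",
    haldane: bool = False,
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The p-value comes from the hypergeometric distribution of cell ``a``
    conditional on the margins.  ``greater`` sums ``P(X >= a)`` (tests
    overrepresentation, the default throughout the pipeline); ``two_sided``
    sums the probabilities of all tables at least as extreme as the
    observed one (point probability <= observed, the standard convention).

    Parameters
    ----------
    haldane
        Apply the Haldane-Anscombe +0.5 correction to the odds ratio only
        (the p-value is always exact).  Off by default.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    # X ~ Hypergeom(M=N, n=row1 total, N=col1 total), observed X = a
    M = table.n
    n_row = a + b
    n_col = a + c
    if alternative == "greater":
        p = float(sps.hypergeom.sf(a - 1, M, n_row, n_col))
    else:
        support = np.arange(max(0, n_row + n_col - M), min(n_row, n_col) + 1)
        pmf = sps.hypergeom.pmf(support, M, n_row, n_col)
        p_obs = pmf[int(a - support[0])]
        # 1+1e-7 relative tolerance guards against floating-point ties,
        # matching the convention of mainstream implementations
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, max(0.0, p))
    if haldane:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = table.odds_ratio()
    return TestResult(odds_ratio=orat, p_value=p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values clipped at 1, aligned with the input order.
    Raises on values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


@dataclass
class LogisticFit:
    """Result of a maximum-likelihood logistic regression.

    ``coefficients`` etc. are keyed by design-column name; ``converged`` is
    False when IRLS hit the iteration cap or the fit shows signs of
    separation, in which case Wald inference should not be trusted.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    separation: bool = False
    n_obs: int = 0
    diagnostics: str = ""

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.coefficients[term]))


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # stable form: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
):
    """Raw IRLS loop for a logit-link binomial GLM.

    Returns ``(beta, se, converged, separation)``.  Convergence is a
    log-likelihood change below ``tol``; the fit is flagged as separated
    when any coefficient magnitude exceeds ``SEPARATION_BETA`` (the MLE
    is then at infinity for practical purposes and Wald inference is
    meaningless).  A warm ``start`` greatly cuts iteration counts when
    fitting many closely related models.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    ll_old = _log_likelihood(y, X @ beta)
    converged = False
    separation = False
    xtwx = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        xtwx = X.T @ xw
        try:
            beta = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False, True
        ll = _log_likelihood(y, X @ beta)
        if np.any(np.abs(beta) > SEPARATION_BETA) or not np.isfinite(ll):
            separation = True
            break
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    # observed information at the final estimate
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separation = True
    return beta, se, converged and not separation, separation


def batched_exposure_irls(
    y: np.ndarray,
    C: np.ndarray,
    E: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """IRLS for M logistic models sharing the response and covariates.

    Model m has design ``[C | E[:, m]]`` — the common covariate block
    plus one exposure column — exactly the situation of the pairwise
    comorbidity scan, where one disease is regressed on each candidate
    partner in turn.  All M fits run in lockstep with vectorized
    iterations; the estimates are identical (same update, same
    log-likelihood stopping rule, same separation flag) to running
    :func:`irls_logistic` once per model.

    Returns ``(beta, se, converged, separation)`` with shapes
    (M, k+1), (M, k+1), (M,), (M,).
    """
    n, k = C.shape
    M = E.shape[1]
    p = k + 1
    CC = np.einsum("ti,tj->tij", C, C).reshape(n, k * k)
    B = np.zeros((M, p)) if start is None else np.array(start, dtype=float)
    active = np.ones(M, dtype=bool)
    converged = np.zeros(M, dtype=bool)
    separation = np.zeros(M, dtype=bool)
    eta = C @ B[:, :k].T + E * B[:, k]
    ll_old = np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
    H = np.zeros((M, p, p))
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        eta_a = eta[:, idx]
        mu = expit(eta_a)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta_a + (y[:, None] - mu) / w
        wE = w * E[:, idx]
        Ha = np.empty((len(idx), p, p))
        Ha[:, :k, :k] = (CC.T @ w).T.reshape(len(idx), k, k)
        cwx = C.T @ wE  # (k, m)
        Ha[:, :k, k] = cwx.T
        Ha[:, k, :k] = cwx.T
        Ha[:, k, k] = np.sum(wE * E[:, idx], axis=0)
        g = np.empty((len(idx), p))
        g[:, :k] = (C.T @ (w * z)).T
        g[:, k] = np.sum(wE * z, axis=0)
        try:
            B_new = np.linalg.solve(Ha, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # fall back model by model to isolate the singular fits
            B_new = np.empty((len(idx), p))
            for r, m in enumerate(idx):
                X = np.column_stack([C, E[:, m]])
                b, _, _, sep = irls_logistic(y, X, max_iter=max_iter, tol=tol,
                                             start=B[m])
                B_new[r] = b
                separation[m] |= sep
        B[idx] = B_new
        eta_a = C @ B[idx, :k].T + E[:, idx] * B[idx, k]
        eta[:, idx] = eta_a
        ll = np.sum(y[:, None] * eta_a - np.logaddexp(0.0, eta_a), axis=0)
        sep_now = np.any(np.abs(B[idx]) > SEPARATION_BETA, axis=1) | ~np.isfinite(ll)
        conv_now = np.abs(ll - ll_old[idx]) < tol
        separation[idx] |= sep_now
        converged[idx] |= conv_now & ~sep_now
        ll_old[idx] = ll
        active[idx] = ~(conv_now | sep_now)
        H[idx] = Ha
    # standard errors from the information at the final estimate
    eta = C @ B[:, :k].T + E * B[:, k]
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    wE = w * E
    H[:, :k, :k] = (CC.T @ w).T.reshape(M, k, k)
    cwx = C.T @ wE
    H[:, :k, k] = cwx.T
    H[:, k, :k] = cwx.T
    H[:, k, k] = np.sum(wE * E, axis=0)
    se = np.full((M, p), np.nan)
    ok = np.flatnonzero(~separation)
    if len(ok):
        try:
            cov = np.linalg.inv(H[ok])
            se[ok] = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
        except np.linalg.LinAlgError:
            for m in ok:
                try:
                    se[m] = np.sqrt(np.clip(np.diag(np.linalg.inv(H[m])), 0.0, None))
                except np.linalg.LinAlgError:
                    separation[m] = True
    converged = converged & ~separation
    return B, se, converged, separation


def fit_logistic(
    response,
    design,
    max_iter: int = 100,
    tol: float = 1e-8,
    start=None,
) -> LogisticFit:
    """Fit a binomial GLM (logit link) by iteratively reweighted least squares.

    Parameters
    ----------
    response : array-like of 0/1
    design : pandas.DataFrame or 2-D array
        Covariate matrix.  An intercept column is prepended automatically
        when no constant column is present.  Column names key the
        returned coefficient maps.
    start : array-like, optional
        Warm-start coefficient vector (length must match the final
        design including the intercept).

    Raises
    ------
    ValueError
        If the response is constant ("degenerate outcome") or lengths
        disagree.
    """
    y = np.asarray(response, dtype=float)
    if hasattr(design, "columns"):
        names = [str(c) for c in design.columns]
        Xv = np.asarray(design, dtype=float)
    else:
        Xv = np.asarray(design, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if y.shape[0] != Xv.shape[0]:
        raise ValueError("response length does not match design rows")
    if np.unique(y).size < 2:
        raise ValueError("degenerate outcome: response is constant")
    if not np.any(np.ptp(Xv, axis=0) == 0):  # no intercept column present
        Xv = np.column_stack([np.ones(Xv.shape[0]), Xv])
        names = ["const", *names]

    beta, se, converged, separation = irls_logistic(
        y, Xv, max_iter=max_iter, tol=tol, start=start
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
        pvals = 2.0 * sps.norm.sf(np.abs(z))
    if not converged:
        pvals = np.full_like(pvals, np.nan)
    return LogisticFit(
        coefficients=dict(zip(names, map(float, beta))),
        standard_errors=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        converged=converged,
        separation=separation,
        n_obs=int(y.shape[0]),
        diagnostics="" if converged else "max-iterations or separation",
    )
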