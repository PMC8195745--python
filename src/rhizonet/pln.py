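"""Sparse Poisson log-normal (PLN) network inference.

Counts are modelled as conditionally Poisson around an exponentiated
latent multivariate Gaussian with known per-sample log offsets:

    Z_i ~ MVN(mu, Sigma),   Y_ij | Z_i ~ Poisson(exp(o_i + Z_ij)).

The latent precision matrix Theta = Sigma^{-1} encodes conditional
(partial-correlation) dependencies between OTUs; an L1 penalty on its
off-diagonal makes the estimate sparse. Fitting maximizes a variational
evidence lower bound (ELBO) with an independent-Gaussian variational
family per observation, alternating an L-BFGS step on the variational
parameters with an exact M-step (closed-form means, penalized
inverse-covariance via the graphical lasso).

The maximized penalized ELBO is monotone across iterations; the model
criteria (BIC, nested pseudo-R²) and the signed partial-correlation
network are derived from the converged fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .containers import CountTable, SignedNetwork, canonical_pair

__all__ = [
    "PLNFit",
    "ModelCriteria",
    "SparsePrecision",
    "PartialCorrelationMatrix",
    "ConvergenceError",
    "fit_pln",
    "precision_path",
    "partial_correlation",
    "threshold_network",
    "model_r2",
    "default_offsets",
    "penalty_grid",
]


class ConvergenceError(RuntimeError):
    """Raised when the variational EM does not converge; carries the ELBO trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelCriteria:
    """Goodness-of-fit summaries of one penalized PLN fit."""

    loglik: float  # maximized ELBO (unpenalized)
    bic: float
    pseudo_r2: float
    n_params: int


@dataclass
class SparsePrecision:
    """Estimated latent precision Theta, its inverse Sigma, and the support."""

    otu_ids: list[str]
    theta: np.ndarray
    sigma: np.ndarray
    penalty: float
    support: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.support:
            self.support = support_pairs(self.theta, self.otu_ids)


@dataclass
class PartialCorrelationMatrix:
    """Symmetric partial-correlation matrix r_jk = -Theta_jk / sqrt(Theta_jj Theta_kk)."""

    otu_ids: list[str]
    r: np.ndarray


@dataclass
class PLNFit:
    """Converged variational PLN fit at one penalty."""

    precision: SparsePrecision
    criteria: ModelCriteria
    mu: np.ndarray
    latent_means: np.ndarray      # n × p variational means of Z
    latent_vars: np.ndarray       # n × p variational variances
    offsets: np.ndarray
    elbo_trace: list[float]
    latent_covariance: np.ndarray  # the M-step input S (before penalization)


def support_pairs(theta: np.ndarray, otu_ids: list[str],
                  atol: float = 1e-10) -> set[tuple[str, str]]:
    p = theta.shape[0]
    out = set()
    for j in range(p):
        for k in range(j + 1, p):
            if abs(theta[j, k]) > atol:
                out.add(canonical_pair(otu_ids[j], otu_ids[k]))
    return out


def default_offsets(table: CountTable) -> np.ndarray:
    """Log of per-sample total counts, the standard PLN depth offset."""
    totals = table.sample_totals.astype(float)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"samples with zero total count: {bad}")
    return np.log(totals)


# ----------------------------------------------------------------------
_EXP_CLIP = 60.0  # exponent guard; counts this large are out of scope


def _elbo_terms(y, o, m, log_s2, mu, theta, theta_logdet):
    """Unpenalized ELBO and its gradients w.r.t. m and log s²."""
    n, p = y.shape
    s2 = np.exp(log_s2)
    eta = np.clip(o[:, None] + m + s2 / 2.0, -_EXP_CLIP, _EXP_CLIP)
    a = np.exp(eta)
    centred = m - mu[None, :]
    quad = centred @ theta
    elbo = (
        np.sum(y * (o[:, None] + m) - a - gammaln(y + 1.0))
        + 0.5 * n * theta_logdet
        - 0.5 * np.sum(quad * centred)
        - 0.5 * np.sum(np.diag(theta)[None, :] * s2)
        + 0.5 * np.sum(log_s2)
        + 0.5 * n * p
    )
    grad_m = y - a - quad
    grad_log_s2 = 0.5 * (1.0 - s2 * (a + np.diag(theta)[None, :]))
    return elbo, grad_m, grad_log_s2


def _estep(y, o, m, log_s2, mu, theta, maxiter=300):
    """Maximize the ELBO over variational parameters by L-BFGS."""
    n, p = y.shape
    sign, theta_logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("precision lost positive definiteness during fitting")

    def fun(x):
        mm = x[: n * p].reshape(n, p)
        ls = x[n * p:].reshape(n, p)
        elbo, gm, gs = _elbo_terms(y, o, mm, ls, mu, theta, theta_logdet)
        return -elbo, -np.concatenate([gm.ravel(), gs.ravel()])

    x0 = np.concatenate([m.ravel(), log_s2.ravel()])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7})
    m_new = res.x[: n * p].reshape(n, p)
    ls_new = res.x[n * p:].reshape(n, p)
    return m_new, ls_new, -res.fun


def _glasso(s: np.ndarray, alpha: float, cov_init: np.ndarray | None = None,
            tol: float = 1e-3, max_iter: int = 100):
    """Graphical lasso with warm start; falls back to the public API."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            from sklearn.covariance import _graph_lasso as _gl

            out = _gl._graphical_lasso(
                s, alpha=alpha, cov_init=cov_init, mode="cd", tol=tol,
                enet_tol=1e-4, max_iter=max_iter, verbose=False,
                eps=np.finfo(float).eps,
            )
            return out[0], out[1]
        except (ImportError, AttributeError, TypeError):
            from sklearn.covariance import graphical_lasso

            cov, prec = graphical_lasso(s, alpha=alpha, tol=tol,
                                        max_iter=max_iter)
            return cov, prec


def _invert_spd(s: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric matrix, ridging until positive definite."""
    p = s.shape[0]
    ridge = 0.0
    for _ in range(40):
        try:
            c = np.linalg.cholesky(s + ridge * np.eye(p))
            ident = np.eye(p)
            inv_c = np.linalg.solve(c, ident)
            return inv_c.T @ inv_c
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8)
    raise np.linalg.LinAlgError("could not invert latent covariance")


def standardize_cov(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and the scale vector of a covariance matrix."""
    d = np.sqrt(np.diag(s))
    c = s / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c, d


def _mstep(m, s2, penalty, cov_init=None):
    # The L1 penalty is applied on the latent *correlation* scale so a
    # single penalty value means the same partial-correlation cutoff for
    # every OTU pair regardless of marginal latent variance.
    n = m.shape[0]
    mu = m.mean(axis=0)
    centred = m - mu[None, :]
    s = centred.T @ centred / n + np.diag(s2.mean(axis=0))
    if penalty > 0 and m.shape[1] > 1:
        c, d = standardize_cov(s)
        cov_c, theta_c = _glasso(c, penalty, cov_init=cov_init)
        theta = theta_c / np.outer(d, d)
        cov = cov_c * np.outer(d, d)
        cov_c_next = cov_c
    else:
        theta = _invert_spd(s)
        cov = s
        cov_c_next = None
    return mu, theta, cov, s, cov_c_next


def _offdiag_l1(theta: np.ndarray) -> float:
    return float(np.sum(np.abs(theta)) - np.sum(np.abs(np.diag(theta))))


def fit_pln(
    table: CountTable,
    offsets: np.ndarray | None = None,
    penalty: float = 0.0,
    *,
    tol: float = 1e-4,
    max_iter: int = 200,
    init: "PLNFit | None" = None,
    on_nonconvergence: str = "raise",
) -> PLNFit:
    """Fit the penalized PLN model to a count table.

    ``offsets`` default to log sample totals. ``penalty`` is the L1
    weight on off-diagonal precision entries (0 = dense fit). ``init``
    warm-starts from a previous fit (used along penalty paths).
    Convergence is declared when the relative change of the penalized
    ELBO drops below ``tol``; the ELBO trace is monotone non-decreasing
    up to numerical tolerance.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    y = table.counts.T.astype(float)  # n × p
    n, p = y.shape
    if n < 2:
        raise ValueError("at least two samples are required")
    o = default_offsets(table) if offsets is None else np.asarray(offsets, float)
    if o.shape != (n,) or not np.all(np.isfinite(o)):
        raise ValueError("offsets must be a finite vector with one entry per sample")

    warm_c: np.ndarray | None = None
    if init is not None:
        m = init.latent_means.copy()
        log_s2 = np.log(init.latent_vars)
        mu = init.mu.copy()
        theta = init.precision.theta.copy()
    else:
        m = np.log(y + 1.0) - o[:, None]
        log_s2 = np.full((n, p), np.log(0.1))
        mu, theta, _, _, warm_c = _mstep(m, np.exp(log_s2), penalty)

    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    trace: list[float] = []
    prev = -np.inf
    converged = False
    s = None
    for _ in range(max_iter):
        m, log_s2, _ = _estep(y, o, m, log_s2, mu, theta)
        mu, theta, cov, s, warm_c = _mstep(m, np.exp(log_s2), penalty,
                                           cov_init=warm_c)
        sign, logdet = np.linalg.slogdet(theta)
        elbo, _, _ = _elbo_terms(y, o, m, log_s2, mu, theta, logdet)
        d_scale = np.sqrt(np.diag(s))
        pen_elbo = elbo - 0.5 * n * penalty * _offdiag_l1(
            theta * np.outer(d_scale, d_scale))
        trace.append(float(pen_elbo))
        if np.isfinite(prev) and pen_elbo - prev < tol * (abs(prev) + 1e-3):
            converged = True
            break
        prev = pen_elbo
    if not converged:
        msg = (f"PLN fit did not converge in {max_iter} iterations "
               f"(last ELBO change {trace[-1] - prev:.3g})")
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg, trace)
        if on_nonconvergence == "warn":
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    otu_ids = list(table.otu_ids)
    sigma = _invert_spd(theta)
    prec = SparsePrecision(otu_ids, theta, sigma, penalty)
    sign, logdet = np.linalg.slogdet(theta)
    elbo, _, _ = _elbo_terms(y, o, m, log_s2, mu, theta, logdet)
    crit = _criteria(y, o, float(elbo), prec)
    return PLNFit(
        precision=prec, criteria=crit, mu=mu,
        latent_means=m, latent_vars=np.exp(log_s2), offsets=o,
        elbo_trace=trace, latent_covariance=s,
    )


def _poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(lam), 0.0)
    return float(np.sum(term - lam - gammaln(y + 1.0)))


def null_loglik(y: np.ndarray, o: np.ndarray) -> float:
    """Poisson log-likelihood of the intercept+offset-only model."""
    b = y.sum(axis=0) / np.exp(o).sum()
    lam = np.exp(o)[:, None] * b[None, :]
    return _poisson_loglik(y, np.maximum(lam, 1e-300))


def saturated_loglik(y: np.ndarray) -> float:
    """Poisson log-likelihood with one rate per observation (lambda = y)."""
    return _poisson_loglik(y, np.maximum(y, 1e-300))


def _criteria(y, o, elbo: float, prec: SparsePrecision) -> ModelCriteria:
    n, p = y.shape
    ll_null = null_loglik(y, o)
    ll_sat = saturated_loglik(y)
    if ll_sat - ll_null <= 0:
        raise ValueError("degenerate data: saturated and null likelihoods coincide")
    r2 = (elbo - ll_null) / (ll_sat - ll_null)
    clipped = min(1.0, max(0.0, r2))
    n_params = 2 * p + len(prec.support)
    bic = elbo - 0.5 * n_params * np.log(n)
    return ModelCriteria(loglik=elbo, bic=float(bic), pseudo_r2=float(clipped),
                         n_params=n_params)


# ----------------------------------------------------------------------
def penalty_grid(latent_cov: np.ndarray, n_values: int = 30,
                 min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty grid.

    Starts at the smallest penalty yielding an empty support (the
    largest off-diagonal magnitude of the latent *correlation* matrix,
    since penalization operates on the correlation scale) and spans
    down to ``min_ratio`` times that value.
    """
    c, _ = standardize_cov(np.asarray(latent_cov, dtype=float))
    off = np.abs(c - np.diag(np.diag(c)))
    alpha_max = float(off.max())
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * min_ratio, n_values)


def precision_path(
    table: CountTable,
    offsets: np.ndarray | None = None,
    penalties: np.ndarray | None = None,
    *,
    n_penalties: int = 30,
    max_iter_warm: int = 30,
    **fit_kwargs,
) -> list[PLNFit]:
    """One PLN fit per penalty, warm-started along a decreasing grid.

    Support size is non-decreasing along the path in the typical case;
    violations (possible with warm starts on hard data) are logged, not
    raised.
    """
    import logging

    logger = logging.getLogger(__name__)
    if penalties is None:
        probe = fit_pln(table, offsets=offsets, penalty=1e6,
                        on_nonconvergence="warn", **fit_kwargs)
        penalties = penalty_grid(probe.latent_covariance, n_penalties)
    penalties = np.asarray(penalties, dtype=float)
    if penalties.ndim != 1 or len(penalties) == 0 or np.any(penalties < 0):
        raise ValueError("penalties must be a non-negative vector")
    if len(penalties) > 1 and np.any(np.diff(penalties) >= 0):
        raise ValueError("penalties must be strictly decreasing (sparse to dense)")

    fits: list[PLNFit] = []
    prev: PLNFit | None = None
    for idx, pen in enumerate(penalties):
        try:
            fit = fit_pln(table, offsets=offsets, penalty=float(pen),
                          init=prev,
                          max_iter=max_iter_warm if prev is not None else 200,
                          on_nonconvergence="warn", **fit_kwargs)
        except Exception as exc:
            raise RuntimeError(f"path fit failed at penalty index {idx} "
                               f"(penalty {pen:.4g})") from exc
        if fits and len(fit.precision.support) < len(fits[-1].precision.support):
            logger.info("support size decreased at penalty %.4g", pen)
        fits.append(fit)
        prev = fit
    return fits


def model_r2(criteria: list[ModelCriteria]) -> float:
    """Pseudo-R² of the BIC-selected model along a criteria path."""
    if not criteria:
        raise ValueError("empty criteria path")
    best = max(criteria, key=lambda c: c.bic)
    return best.pseudo_r2


# ----------------------------------------------------------------------
def partial_correlation(prec: SparsePrecision | np.ndarray,
                        otu_ids: list[str] | None = None) -> PartialCorrelationMatrix:
    """Signed partial correlations r_jk = -Theta_jk / sqrt(Theta_jj Theta_kk)."""
    if isinstance(prec, SparsePrecision):
        theta = prec.theta
        otu_ids = prec.otu_ids
    else:
        theta = np.asarray(prec, dtype=float)
        if otu_ids is None:
            otu_ids = [str(i) for i in range(theta.shape[0])]
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision has non-positive diagonal entries")
    scale = 1.0 / np.sqrt(d)
    r = -theta * scale[:, None] * scale[None, :]
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return PartialCorrelationMatrix(list(otu_ids), r)


def threshold_network(
    parcor: PartialCorrelationMatrix,
    min_abs_r: float = 0.06,
    stability: dict[tuple[str, str], float] | None = None,
    min_frequency: float = 0.9,
    name: str = "",
) -> SignedNetwork:
    """Call edges from a partial-correlation matrix.

    An edge (j, k) is retained iff ``|r_jk| > min_abs_r`` and — when
    StARS selection frequencies are supplied — its frequency is at
    least ``min_frequency``. Edge weight is the partial correlation;
    isolated nodes are dropped (nodes are edge endpoints only).
    """
    if not 0 <= min_abs_r < 1:
        raise ValueError("min_abs_r must be in [0, 1)")
    ids = parcor.otu_ids
    edges: dict[tuple[str, str], float] = {}
    freq: dict[tuple[str, str], float] = {}
    p = len(ids)
    for j in range(p):
        for k in range(j + 1, p):
            r = parcor.r[j, k]
            if abs(r) <= min_abs_r or r == 0:
                continue
            pair = canonical_pair(ids[j], ids[k])
            if stability is not None:
                f = stability.get(pair, 0.0)
                if f < min_frequency:
                    continue
                freq[pair] = f
            edges[pair] = float(r)
    return SignedNetwork(name=name, edges=edges, stability=freq)
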