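"""Batched weighted logistic regression by Newton-Raphson.

The permutation multiplicity procedure refits 31 small age-adjusted
logistic models per permutation, i.e. hundreds of thousands of 3-parameter
fits per run; the power simulator refits one model per replicate.  This
module solves stacks of such problems simultaneously with vectorised
Newton iterations (batched matmuls and one batched p×p solve per
iteration).  Problems that finish — converged, separated or singular —
are retired from the working arrays each iteration, so a few slow
problems cannot force full-batch work for the whole iteration budget.

Numerics: zero start, step-halving on log-likelihood decrease, convergence
on max |score| < tol, quasi-separation flagged at |linear predictor| > 30.
Case weights of 0 implement per-problem complete-case exclusion so all
problems can share one rectangular array.  The solver is cross-checked
against statsmodels and a direct scipy.optimize likelihood maximisation
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["BatchLogitFit", "fit_logistic_batch"]

_MAX_ETA = 30.0  # |linear predictor| beyond this flags quasi-separation


@dataclass
class BatchLogitFit:
    """Stacked fit results: arrays indexed by problem.

    beta : (S, p) coefficient estimates
    cov : (S, p, p) inverse observed information
    loglik : (S,) maximised log-likelihood
    converged : (S,) bool
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray

    def se(self) -> np.ndarray:
        return np.sqrt(np.einsum("spp->sp", self.cov))

    def wald_p(self) -> np.ndarray:
        """Two-sided Wald p-values per coefficient, shape (S, p)."""
        from scipy.stats import norm

        z = self.beta / self.se()
        return 2.0 * norm.sf(np.abs(z))


def _loglik_from_mu(y: np.ndarray, eta: np.ndarray, mu: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    # y*eta - softplus(eta), with softplus(eta) = -log(1 - mu); clip the
    # complement away from 0 so separated problems yield -inf-free values
    comp = np.clip(1.0 - mu, 1e-300, None)
    return np.sum(w * (y * eta + np.log(comp)), axis=-1)


def _batch_inv(info: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked p×p inverse; singular problems get NaN and a flag."""
    S, p, _ = info.shape
    cov = np.full((S, p, p), np.nan)
    singular = np.zeros(S, dtype=bool)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        for s in range(S):
            try:
                cov[s] = np.linalg.inv(info[s])
            except np.linalg.LinAlgError:
                singular[s] = True
    bad = ~np.isfinite(cov).all(axis=(1, 2))
    singular |= bad
    cov[bad] = np.nan
    return cov, singular


def fit_logistic_batch(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> BatchLogitFit:
    """Fit S logistic regressions y ~ X[s] simultaneously.

    Parameters
    ----------
    y : (n,) or (S, n) binary responses (shared or per-problem).
    X : (S, n, p) or (n, p) design matrices (shared design is broadcast).
    weights : optional (S, n) or (n,) nonnegative case weights; a zero
        weight removes the row from that problem.

    Returns
    -------
    BatchLogitFit with per-problem coefficients, covariance, log-likelihood
    and convergence flags.  Non-convergence (separation, singular
    information) is flagged, never raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    S, n, p = X.shape
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = np.broadcast_to(y, (S, n))
    if weights is None:
        w = np.ones((S, n))
    else:
        w = np.asarray(weights, dtype=float)
        if w.ndim == 1:
            w = np.broadcast_to(w, (S, n))

    # output arrays (global problem indexing)
    beta_out = np.zeros((S, p))
    ll_out = np.full(S, np.nan)
    conv_out = np.zeros(S, dtype=bool)

    # working (compacted) state
    idx = np.arange(S)
    Xw = X
    yw = np.ascontiguousarray(y, dtype=float)
    ww = np.ascontiguousarray(w, dtype=float)
    Xt = np.ascontiguousarray(Xw.transpose(0, 2, 1))
    m = S
    beta = np.zeros((m, p))
    eta = np.zeros((m, n))
    mu = np.full((m, n), 0.5)
    ll = _loglik_from_mu(yw, eta, mu, ww)
    singular = np.zeros(m, dtype=bool)

    def _retire(mask: np.ndarray, conv: np.ndarray) -> None:
        nonlocal idx, Xw, yw, ww, Xt, beta, eta, mu, ll, singular, m
        gids = idx[mask]
        beta_out[gids] = beta[mask]
        ll_out[gids] = ll[mask]
        conv_out[gids] = conv[mask]
        keep = ~mask
        idx = idx[keep]
        Xw, yw, ww, Xt = Xw[keep], yw[keep], ww[keep], Xt[keep]
        beta, eta, mu, ll = beta[keep], eta[keep], mu[keep], ll[keep]
        singular = singular[keep]
        m = len(idx)

    for _ in range(max_iter):
        if m == 0:
            break
        resid = ww * (yw - mu)
        grad = np.matmul(Xt, resid[:, :, None])[:, :, 0]
        gconv = np.abs(grad).max(axis=1) < tol
        sep = (np.abs(eta) * (ww > 0)).max(axis=1) > _MAX_ETA
        finished = gconv | sep | singular
        if finished.any():
            _retire(finished, gconv & ~sep & ~singular)
            if m == 0:
                break
            resid = ww * (yw - mu)
            grad = np.matmul(Xt, resid[:, :, None])[:, :, 0]
        wvar = ww * mu * (1.0 - mu)
        info = np.matmul(Xt * wvar[:, None, :], Xw)
        step = np.zeros_like(beta)
        try:
            step = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for s in range(m):
                try:
                    step[s] = np.linalg.solve(info[s], grad[s])
                except np.linalg.LinAlgError:
                    singular[s] = True
                    step[s] = 0.0
        bad_step = ~np.isfinite(step).all(axis=1)
        if bad_step.any():
            singular |= bad_step
            step[bad_step] = 0.0
        # step-halving where the likelihood would decrease; the final pass
        # evaluates every problem at its final factor, so its candidate
        # state is reused directly
        factor = np.ones(m)
        for _half in range(25):
            cand = beta + factor[:, None] * step
            eta_c = np.matmul(Xw, cand[:, :, None])[:, :, 0]
            mu_c = expit(eta_c)
            ll_c = _loglik_from_mu(yw, eta_c, mu_c, ww)
            worse = ~singular & (ll_c < ll - 1e-12)
            if not worse.any():
                break
            factor[worse] *= 0.5
        beta, eta, mu, ll = cand, eta_c, mu_c, ll_c

    if m:  # iteration budget exhausted: flagged non-converged
        _retire(np.ones(m, dtype=bool), np.zeros(m, dtype=bool))

    # one full pass for the covariance at the final coefficients
    eta_f = np.einsum("snp,sp->sn", X, beta_out)
    mu_f = expit(eta_f)
    wvar = w * mu_f * (1.0 - mu_f)
    info = np.einsum("snp,sn,snq->spq", X, wvar, X)
    cov, sing_f = _batch_inv(info)
    conv_out = conv_out & ~sing_f
    return BatchLogitFit(beta=beta_out, cov=cov, loglik=ll_out,
                         converged=conv_out)
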