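"""Logistic mixed model association: one PQL null fit, then score tests.

The trait model is Bernoulli with logit link,

    logit P(Y_i = 1) = mu + sum_k beta_k PC_ik + alpha x_i + Line_i,
    (Line_1, ..., Line_n) ~ MVN(0, 2 K sigma_G^2),

where K is the additive kinship matrix.  Fitting the full model at every
marker is unnecessary: the null model (alpha = 0) is fitted once by penalized
quasi-likelihood (PQL), and each marker is then evaluated with a score test
that reuses the cached null projection — the strategy introduced for
genome-scale binary-trait association by the GMMAT method.

PQL iterates a working linear mixed model: given current eta and
mu = expit(eta), the working response is z = eta + (y - mu)/W with weights
W = mu(1 - mu), and z = X beta + b + e with Var(b) = 2 sigma_G^2 K and
Var(e) = W^{-1} is refitted, updating sigma_G^2 by REML of the working model
each cycle.  At convergence y - mu = P z with P the covariate-projected
inverse of Sigma = W^{-1} + 2 sigma_G^2 K, so the per-marker score statistic
is T^2/V with T = g'(y - mu) and V = g' P g, referred to chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .geno_io import GenotypeMatrix, allele_frequency
from .popstruct import CovariateSet, KinshipMatrix

log = logging.getLogger(__name__)

#: fitted probabilities beyond this range flag quasi-separation
_SEP_EPS = 1e-10
#: score-variance floor below which a marker is reported as not tested
MIN_SCORE_VAR = 1e-12


class ConvergenceError(RuntimeError):
    """PQL failed to converge; ``last_fit`` carries the final iterate."""

    def __init__(self, msg: str, last_fit: "LMMNullFit | None" = None):
        super().__init__(msg)
        self.last_fit = last_fit


@dataclass
class LMMNullFit:
    """Converged PQL null fit with cached pieces for marker scoring.

    ``P`` is the projected inverse of Sigma = W^{-1} + 2 sigma_G^2 K:
    P = Sigma^{-1} - Sigma^{-1} X (X' Sigma^{-1} X)^{-1} X' Sigma^{-1}.
    """

    beta: np.ndarray          # fixed effects, log-odds scale
    sigma_g2: float           # genetic variance component (link scale)
    mu: np.ndarray            # fitted event probabilities
    weights: np.ndarray       # mu * (1 - mu)
    blup: np.ndarray          # predicted random line effects
    P: np.ndarray             # n x n projected inverse covariance
    y: np.ndarray
    X: np.ndarray
    converged: bool
    n_iter: int
    boundary: bool = False    # sigma_g2 at the zero boundary
    quasi_separated: bool = False


def _working_reml(z, X, W, A_eval_cache):
    """REML estimate of s in Var = s*A + W^{-1} for the working model.

    ``A_eval_cache`` is the (dense, symmetric) matrix A = 2K.  Returns
    (s_hat, Vinv) where Vinv = (s*A + W^{-1})^{-1}, computed through the
    eigendecomposition of B = W^{1/2} A W^{1/2}.
    """
    A = A_eval_cache
    ws = np.sqrt(W)
    B = (ws[:, None] * A) * ws[None, :]
    lam, Q = np.linalg.eigh(B)
    lam = np.maximum(lam, 0.0)
    zt = Q.T @ (ws * z)
    Xt = Q.T @ (ws[:, None] * X)

    def neg_restricted_ll(log_s: float) -> float:
        s = np.exp(log_s)
        d = s * lam + 1.0
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        sign, logdet = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, Xd.T @ zt)
        r = zt - Xt @ beta
        return 0.5 * (np.sum(np.log(d)) + logdet + np.sum(r * r / d))

    # coarse grid then local refinement on log s, compared against s = 0
    grid = np.linspace(-12.0, 6.0, 37)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    s_hat = float(np.exp(res.x))
    # s = 0 limit: plain weighted least squares
    d0 = np.ones_like(lam)
    Xd0 = Xt
    XtVX0 = Xt.T @ Xd0
    beta0 = np.linalg.solve(XtVX0, Xd0.T @ zt)
    r0 = zt - Xt @ beta0
    nll0 = 0.5 * (np.linalg.slogdet(XtVX0)[1] + np.sum(r0 * r0 / d0))
    if nll0 <= res.fun + 1e-10:
        s_hat = 0.0
    d = s_hat * lam + 1.0
    WQ = ws[:, None] * Q
    Vinv = (WQ / d[None, :]) @ WQ.T
    return s_hat, Vinv


def fit_lmm_null(y, X, K, *, kinship_scale: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 100, fix_sigma_g2: float | None = None) -> LMMNullFit:
    """Fit the null logistic mixed model by PQL.

    Parameters
    ----------
    y : 0/1 array (no missing; drop missing-phenotype samples first)
    X : CovariateSet or n x p design array (intercept included)
    K : KinshipMatrix or n x n array
    kinship_scale : float
        Multiplier on K in the line-effect covariance (default 2, i.e.
        Var(Line) = 2 K sigma_G^2).
    fix_sigma_g2 : float, optional
        Skip the REML update and hold sigma_G^2 fixed (0 recovers ordinary
        logistic regression by IRLS).

    Raises
    ------
    ValueError
        If y is not two-class binary or shapes disagree.
    ConvergenceError
        If PQL does not converge within ``max_iter``.
    """
    Xd = X.design if isinstance(X, CovariateSet) else np.asarray(X, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if np.any(np.isnan(y)):
        raise ValueError("missing phenotypes must be dropped before fitting")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("trait must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("trait has a single class; cannot fit")
    if Xd.shape[0] != n or Kv.shape != (n, n):
        raise ValueError("y, X and K must be aligned on the same samples")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("covariate design is rank deficient")

    A = kinship_scale * 0.5 * (Kv + Kv.T)
    p_bar = y.mean()
    beta = np.zeros(Xd.shape[1])
    beta[0] = special.logit(p_bar)
    b = np.zeros(n)
    s = 0.1 if fix_sigma_g2 is None else float(fix_sigma_g2)
    converged = False
    Vinv = None
    for it in range(1, max_iter + 1):
        eta = Xd @ beta + b
        mu = special.expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / W
        if fix_sigma_g2 is None:
            s_new, Vinv = _working_reml(z, Xd, W, A)
        else:
            s_new = float(fix_sigma_g2)
            V = s_new * A + np.diag(1.0 / W)
            Vinv = np.linalg.inv(V)
        XtVinv = Xd.T @ Vinv
        beta_new = np.linalg.solve(XtVinv @ Xd, XtVinv @ z)
        b_new = s_new * (A @ (Vinv @ (z - Xd @ beta_new)))
        delta = max(np.max(np.abs(beta_new - beta)), abs(s_new - s))
        beta, b, s = beta_new, b_new, s_new
        if delta < tol:
            converged = True
            break

    eta = Xd @ beta + b
    mu = special.expit(eta)
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    XtVinvX = Xd.T @ Vinv @ Xd
    P = Vinv - (Vinv @ Xd) @ np.linalg.solve(XtVinvX, Xd.T @ Vinv)
    fit = LMMNullFit(
        beta=beta, sigma_g2=s, mu=mu, weights=W, blup=b, P=P, y=y, X=Xd,
        converged=converged, n_iter=it, boundary=(s == 0.0),
        quasi_separated=bool(np.any(mu < _SEP_EPS) or np.any(mu > 1 - _SEP_EPS)),
    )
    if not converged:
        raise ConvergenceError(f"PQL did not converge in {max_iter} iterations", fit)
    if fit.quasi_separated:
        log.warning("fitted probabilities at machine bounds: possible quasi-separation")
    return fit


def lmm_score_test(fit: LMMNullFit, g) -> tuple[float, float, bool]:
    """Score test of one marker against the cached null fit.

    Returns ``(statistic, p_value, tested)``; markers whose score variance
    g' P g falls below ``MIN_SCORE_VAR`` are flagged not tested.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[0] != fit.y.shape[0]:
        raise ValueError("marker length does not match fitted samples")
    T = g @ (fit.y - fit.mu)
    V = g @ (fit.P @ g)
    if V < MIN_SCORE_VAR:
        return np.nan, np.nan, False
    stat = T * T / V
    return float(stat), float(stats.chi2.sf(stat, 1)), True


def run_lmm_gwas(y, G: GenotypeMatrix, X, K, *, kinship_scale: float = 2.0,
                 fdr_levels=(0.05, 0.10)) -> pd.DataFrame:
    """Genome-wide score tests: one association-table row per marker.

    The returned frame (an "AssocTable") has columns marker, chrom, pos, maf,
    stat, p, tested, model, plus Benjamini-Hochberg calls per FDR level;
    the genomic-control lambda over tested markers is stored in
    ``table.attrs["lambda_gc"]``.
    """
    from . import diagnostics

    fit = fit_lmm_null(y, X, K, kinship_scale=kinship_scale)
    calls = G.calls.astype(float)
    resid = fit.y - fit.mu
    T = calls.T @ resid
    PG = fit.P @ calls
    V = np.einsum("ij,ij->j", calls, PG)
    tested = V >= MIN_SCORE_VAR
    stat = np.full(G.n_markers, np.nan)
    stat[tested] = T[tested] ** 2 / V[tested]
    p = np.full(G.n_markers, np.nan)
    p[tested] = stats.chi2.sf(stat[tested], 1)
    table = pd.DataFrame({
        "marker": G.markers, "chrom": G.chrom, "pos": G.pos,
        "maf": allele_frequency(G).maf,
        "stat": stat, "p": p, "tested": tested, "model": "LMM",
    })
    diagnostics.add_fdr(table, fdr_levels)
    table.attrs["lambda_gc"] = diagnostics.genomic_control(stat[tested])
    table.attrs["null_fit"] = fit
    return table
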