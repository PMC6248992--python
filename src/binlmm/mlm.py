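"""Unified mixed linear model association with P3D variance components.

The comparison arm: the trait (binary traits included, deliberately treated
as continuous 0/1 responses) is modeled as

    y = X beta + u + e,   Var(u) = 2 sigma_g^2 K,   Var(e) = sigma_e^2 I,

with PC covariates in X and kinship K.  Variance components are estimated
once by REML under the null ("population parameters previously determined",
P3D) and reused for every marker, where a generalized-least-squares Wald
t-test evaluates the marker effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno_io import GenotypeMatrix, allele_frequency
from .popstruct import CovariateSet, KinshipMatrix

#: squared norm of a projected marker below which it is reported untested
MIN_MARKER_SS = 1e-10


@dataclass
class MLMNullFit:
    """REML null fit: variance components plus the cached spectral factors.

    ``eigvals``/``eigvecs`` decompose A = 2K, so Var(y) = sigma_g2 * A +
    sigma_e2 * I is diagonal in the eigenbasis with entries
    v_i = sigma_g2 * d_i + sigma_e2.
    """

    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    reml_ll: float
    n: int
    p: int


def _restricted_ll(vg: float, ve: float, d, yr, Xr) -> float:
    """Restricted log-likelihood (additive constants dropped) in the eigenbasis."""
    v = vg * d + ve
    if np.any(v <= 0):
        return -np.inf
    Xv = Xr / v[:, None]
    XtVX = Xr.T @ Xv
    sign, logdet = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, Xv.T @ yr)
    r = yr - Xr @ beta
    return -0.5 * (np.sum(np.log(v)) + logdet + np.sum(r * r / v))


def fit_mlm_null(y, X, K, *, kinship_scale: float = 2.0,
                 log_delta_bounds: tuple[float, float] = (-10.0, 10.0)) -> MLMNullFit:
    """REML fit of the null mixed linear model.

    The profiled restricted likelihood is maximized over the variance ratio
    delta = sigma_e^2 / sigma_g^2 on a log grid plus Brent refinement within
    ``log_delta_bounds``; the boundary model sigma_g^2 = 0 is evaluated with
    the same criterion and wins ties, so unidentifiable or null-leaning data
    land on the boundary rather than an arbitrary interior ratio.
    """
    Xd = X.design if isinstance(X, CovariateSet) else np.asarray(X, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    if np.any(np.isnan(y)):
        raise ValueError("missing phenotypes must be dropped before fitting")
    if y.shape[0] != n or Kv.shape != (n, n):
        raise ValueError("y, X and K must be aligned on the same samples")
    if n <= p + 1:
        raise ValueError("too few samples for the covariate design")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")

    A = kinship_scale * 0.5 * (Kv + Kv.T)
    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    Xr = U.T @ Xd

    def profile(log_delta: float) -> tuple[float, float, float]:
        """Profiled (vg, ve, restricted LL) at a given variance ratio."""
        delta = np.exp(log_delta)
        h = d + delta
        Xh = Xr / h[:, None]
        beta = np.linalg.solve(Xr.T @ Xh, Xh.T @ yr)
        r = yr - Xr @ beta
        vg = float(np.sum(r * r / h) / (n - p))
        ve = delta * vg
        return vg, ve, _restricted_ll(vg, ve, d, yr, Xr)

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, 41)
    lls = [profile(g)[2] for g in grid]
    i = int(np.argmax(lls))
    res = optimize.minimize_scalar(
        lambda x: -profile(x)[2],
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-8})
    vg, ve, ll = profile(float(res.x))

    # boundary model: no genetic variance
    Xv = Xr
    beta0 = np.linalg.solve(Xr.T @ Xv, Xv.T @ yr)
    r0 = yr - Xr @ beta0
    ve0 = float(np.sum(r0 * r0) / (n - p))
    ll0 = _restricted_ll(0.0, ve0, d, yr, Xr)
    if ll0 >= ll - 1e-8:
        vg, ve, ll = 0.0, ve0, ll0

    v = vg * d + ve
    Xv = Xr / v[:, None]
    beta = np.linalg.solve(Xr.T @ Xv, Xv.T @ yr)
    return MLMNullFit(beta=beta, sigma_g2=vg, sigma_e2=ve, eigvals=d, eigvecs=U,
                      reml_ll=ll, n=n, p=p)


def _whiten(fit: MLMNullFit):
    """Rows of the whitening transform v^{-1/2} U' (any overall scale cancels
    in the t statistic because the residual scale is re-estimated per marker)."""
    v = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    return fit.eigvecs / np.sqrt(v)[None, :]  # == (v^{-1/2} U')'


def mlm_marker_test(fit: MLMNullFit, g, y, X) -> tuple[float, float, float, bool]:
    """GLS Wald t-test of one marker under the P3D variance components.

    Returns ``(effect, t_statistic, p_value, tested)``.  The marker and trait
    are whitened by the fitted covariance, covariates are projected out, and
    the effect is tested with a t statistic on n - p - 1 df whose residual
    scale is re-estimated per marker (so sigma_g^2 = 0 reduces exactly to the
    ordinary-least-squares t-test).
    """
    Xd = X.design if isinstance(X, CovariateSet) else np.asarray(X, dtype=float)
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    Wt = _whiten(fit)
    yt = Wt.T @ y
    Xt = Wt.T @ Xd
    gt = Wt.T @ g
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    gr = gt - Q @ (Q.T @ gt)
    ss = gr @ gr
    if np.ptp(g) == 0 or ss < MIN_MARKER_SS * max(gt @ gt, 1.0):
        return np.nan, np.nan, np.nan, False
    alpha = (gr @ yr) / ss
    df = fit.n - fit.p - 1
    rss = yr @ yr - alpha * alpha * ss
    se = np.sqrt(max(rss, 0.0) / df / ss)
    t = alpha / se
    return float(alpha), float(t), float(2.0 * stats.t.sf(abs(t), df)), True


def run_mlm_gwas(y, G: GenotypeMatrix, X, K, *, kinship_scale: float = 2.0,
                 fdr_levels=(0.05, 0.10)) -> pd.DataFrame:
    """Genome-wide P3D marker tests; same association-table surface as the LMM."""
    from . import diagnostics

    Xd = X.design if isinstance(X, CovariateSet) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = fit_mlm_null(y, Xd, K, kinship_scale=kinship_scale)
    Wt = _whiten(fit)
    yt = Wt.T @ y
    Xt = Wt.T @ Xd
    Gt = (Wt.T @ G.calls.astype(float))  # n x m in whitened space
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Gr = Gt - Q @ (Q.T @ Gt)
    ss = np.einsum("ij,ij->j", Gr, Gr)
    scale = np.maximum(np.einsum("ij,ij->j", Gt, Gt), 1.0)
    tested = (np.ptp(G.calls, axis=0) > 0) & (ss >= MIN_MARKER_SS * scale)
    df = fit.n - fit.p - 1
    alpha = np.full(G.n_markers, np.nan)
    tstat = np.full(G.n_markers, np.nan)
    p = np.full(G.n_markers, np.nan)
    alpha[tested] = (Gr[:, tested].T @ yr) / ss[tested]
    rss = (yr @ yr) - alpha[tested] ** 2 * ss[tested]
    se = np.sqrt(np.maximum(rss, 0.0) / df / ss[tested])
    tstat[tested] = alpha[tested] / se
    p[tested] = 2.0 * stats.t.sf(np.abs(tstat[tested]), df)
    table = pd.DataFrame({
        "marker": G.markers, "chrom": G.chrom, "pos": G.pos,
        "maf": allele_frequency(G).maf,
        "effect": alpha, "stat": tstat**2, "p": p, "tested": tested, "model": "MLM",
    })
    diagnostics.add_fdr(table, fdr_levels)
    table.attrs["lambda_gc"] = diagnostics.genomic_control(p=table.loc[tested, "p"].to_numpy())
    table.attrs["null_fit"] = fit
    return table
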