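"""Multiple-testing control, genomic control, QQ data, and the
subpopulation-stratified false-positive diagnostic.

The stratified diagnostic partitions markers by the ratio of expected
genotypic variance 2*MAF*(1-MAF) between a focal subpopulation and the other
subpopulation: markers rarer in the focal group (ratio < 0.80), similar
(0.80-1.25, closed interval), and more common in the focal group (> 1.25).
Under a null trait whose prevalence differs between subpopulations, a
misspecified linear model inflates test statistics in the common-in-focal
stratum and deflates them in the rare-in-focal stratum; per-stratum
genomic-control lambdas expose this even when the overall lambda looks benign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geno_io import GenotypeMatrix, allele_frequency

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

STRATA = ("rare_in_focal", "similar", "common_in_focal")


@dataclass
class StratumAssignment:
    """Per-marker variance-ratio stratum plus the underlying subpopulation MAFs."""

    markers: list[str]
    stratum: np.ndarray        # values from STRATA
    maf_focal: np.ndarray
    maf_other: np.ndarray
    ratio: np.ndarray          # 2*maf_f*(1-maf_f) / (2*maf_o*(1-maf_o))
    focal: str


@dataclass
class DiagnosticsReport:
    """Per model x stratum lambdas and counts, plus FDR discovery totals."""

    table: pd.DataFrame        # columns: model, stratum, n_markers, lambda
    fdr_counts: pd.DataFrame   # columns: model, q, n_discoveries
    qq: dict                   # (model, stratum) -> (expected, observed)


def bh_fdr(p, q: float):
    """Benjamini-Hochberg step-up calls at target FDR ``q``.

    NaN entries (not-tested markers) are excluded from the test count and
    returned as False.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    if p.size == 0:
        return out
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return out


def add_fdr(table: pd.DataFrame, levels=(0.05, 0.10)) -> pd.DataFrame:
    """Append BH call columns (fdr05, fdr10, ...) to an association table."""
    for q in levels:
        table[f"fdr{int(round(q * 100)):02d}"] = bh_fdr(table["p"].to_numpy(), q)
    return table


def genomic_control(stats_chi2=None, p=None) -> float:
    """Genomic-control inflation factor from the median test statistic.

    lambda = median(statistic) / median(chi-square_1).  Pass 1-df chi-square
    statistics directly, or p-values (converted through the chi-square(1)
    quantile function).
    """
    if stats_chi2 is not None:
        s = np.asarray(stats_chi2, dtype=float)
    elif p is not None:
        pv = np.asarray(p, dtype=float)
        s = stats.chi2.isf(pv, 1)
    else:
        raise ValueError("provide statistics or p-values")
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no statistics to compute lambda from")
    return float(np.median(s) / CHI2_1_MEDIAN)


def filter_monomorphic_within(G: GenotypeMatrix, labels) -> tuple[GenotypeMatrix, list[str]]:
    """Drop markers that are constant within either of exactly two subpopulations."""
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 subpopulations, got {len(groups)}")
    keep = np.ones(G.n_markers, dtype=bool)
    for gname in groups:
        sub = G.calls[labels == gname, :]
        keep &= np.ptp(sub, axis=0) > 0
    removed = [G.markers[i] for i in np.flatnonzero(~keep)]
    return G.subset_markers(np.flatnonzero(keep)), removed


def variance_ratio_strata(G: GenotypeMatrix, labels, focal: str) -> StratumAssignment:
    """Assign each marker to a stratum by the expected-variance ratio.

    v_s = 2*MAF_s*(1-MAF_s) within each subpopulation; r = v_focal/v_other.
    r < 0.80 -> rare_in_focal, 0.80 <= r <= 1.25 -> similar,
    r > 1.25 -> common_in_focal.  Apply the monomorphic-within filter first so
    both within-subpopulation variances are positive.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 subpopulations, got {len(groups)}")
    if focal not in groups:
        raise ValueError(f"focal subpopulation {focal!r} not among labels {groups}")
    other = groups[0] if groups[1] == focal else groups[1]
    maf_f = allele_frequency(G, np.flatnonzero(labels == focal), label=focal).maf
    maf_o = allele_frequency(G, np.flatnonzero(labels == other), label=other).maf
    v_f = 2.0 * maf_f * (1.0 - maf_f)
    v_o = 2.0 * maf_o * (1.0 - maf_o)
    if np.any(v_o == 0) or np.any(v_f == 0):
        raise RuntimeError("zero within-subpopulation variance: apply "
                           "filter_monomorphic_within first")
    r = v_f / v_o
    stratum = np.where(r < 0.80, STRATA[0], np.where(r > 1.25, STRATA[2], STRATA[1]))
    return StratumAssignment(list(G.markers), stratum.astype(object), maf_f, maf_o,
                             r, focal)


def bernoulli_variance(p_hat: float) -> float:
    """Variance of a Bernoulli trait, p_hat * (1 - p_hat)."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    return p_hat * (1.0 - p_hat)


def qq_points(p) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p-value pairs for a QQ plot.

    Observed values are sorted descending; the i-th expectation (rank i,
    starting at 1) is -log10(i / (m + 1)).
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m == 0:
        return np.array([]), np.array([])
    observed = -np.log10(np.sort(p))
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    return expected, observed


def stratified_diagnostics(lmm: pd.DataFrame, mlm: pd.DataFrame,
                           strata: StratumAssignment,
                           fdr_levels=(0.05, 0.10)) -> DiagnosticsReport:
    """Per model x stratum lambda, QQ points and counts plus overall rows.

    Both association tables and the stratum assignment must index the same
    markers in the same order.
    """
    for tab, name in ((lmm, "lmm"), (mlm, "mlm")):
        if list(tab["marker"]) != list(strata.markers):
            raise ValueError(f"{name} table markers do not match the stratum assignment")
    rows, qq, fdr_rows = [], {}, []
    for tab in (lmm, mlm):
        model = tab["model"].iloc[0]
        tested = tab["tested"].to_numpy()
        pvals = tab["p"].to_numpy()
        use_stats = model == "LMM"  # chi-square(1) score statistics
        svals = tab["stat"].to_numpy()
        for name in ("all",) + STRATA:
            mask = tested if name == "all" else tested & (strata.stratum == name)
            lam = np.nan
            if mask.any():
                lam = (genomic_control(svals[mask]) if use_stats
                       else genomic_control(p=pvals[mask]))
                qq[(model, name)] = qq_points(pvals[mask])
            rows.append({"model": model, "stratum": name,
                         "n_markers": int(mask.sum()), "lambda": lam})
        for q in fdr_levels:
            fdr_rows.append({"model": model, "q": q,
                             "n_discoveries": int(bh_fdr(pvals, q).sum())})
    return DiagnosticsReport(pd.DataFrame(rows), pd.DataFrame(fdr_rows), qq)


def plot_qq(tables: dict[str, pd.DataFrame], path: str) -> None:
    """QQ plot of -log10 p-values for one or more association tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    top = 0.0
    for name, tab in tables.items():
        exp, obs = qq_points(tab.loc[tab["tested"], "p"].to_numpy())
        ax.plot(exp, obs, ".", ms=3, label=f"{name} (lambda={tab.attrs.get('lambda_gc', float('nan')):.2f})")
        if exp.size:
            top = max(top, exp.max(), obs.max())
    ax.plot([0, top], [0, top], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_manhattan(table: pd.DataFrame, path: str) -> None:
    """Manhattan plot of an association table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = table.loc[table["tested"]].copy()
    tab["logp"] = -np.log10(tab["p"])
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for i, (_, grp) in enumerate(tab.groupby("chrom", sort=False)):
        ax.plot(offset + grp["pos"].to_numpy(), grp["logp"], ".", ms=3,
                color=["tab:blue", "tab:orange"][i % 2])
        offset += int(grp["pos"].max()) + 1
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
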