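"""Synthetic structured diversity panels and traits.

Genotypes follow the Balding-Nichols model: each marker draws an ancestral
frequency p uniformly from a stated range, each subpopulation then draws its
own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — so F plays the role of
F_ST — and individuals draw genotypes Binomial(2, p_s).  Traits are either
pure Bernoulli draws with subpopulation-specific prevalence (the type-I-error
design: no genetic component, so every marker is null), Bernoulli with an
optional liability-scale QTN contribution (for power checks), or quantitative
with additive QTN effects and a structure-confounded shift.

The default panel is two subpopulations of 64 ("tropical") and 216
("non-tropical") lines, mirroring a maize diversity panel in which a binary
trait with prevalence 0.5 in the tropical group and 0.05 elsewhere exposes
the unified MLM's loss of type-I-error control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .geno_io import GenotypeMatrix
from . import diagnostics, lmm, mlm, popstruct

log = logging.getLogger(__name__)

DEFAULT_LABELS = ("tropical", "non_tropical")


@dataclass
class SimConfig:
    """Specification of one synthetic panel + trait experiment."""

    n_per_subpop: tuple[int, ...] = (64, 216)
    labels: tuple[str, ...] = DEFAULT_LABELS
    m: int = 5000
    fst: float = 0.3
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    prevalence_map: dict = field(default_factory=lambda: {"tropical": 0.5,
                                                          "non_tropical": 0.05})
    qtn_spec: list = field(default_factory=list)  # [(marker index, effect), ...]
    h2: float = 0.0
    structure_effect: float = 0.0
    n_pcs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_subpop) != len(self.labels):
            raise ValueError("one label per subpopulation size required")
        if any(n < 2 for n in self.n_per_subpop):
            raise ValueError("each subpopulation needs at least 2 samples")
        if self.m < 1:
            raise ValueError("need at least one marker")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if any(not 0 <= v <= 1 for v in self.prevalence_map.values()):
            raise ValueError("prevalences must lie in [0, 1]")


@dataclass
class ExperimentSummary:
    """Aggregated type-I-error experiment results.

    ``per_replicate`` has one row per replicate x model x stratum with its
    genomic-control lambda; ``aggregate`` averages lambdas over replicates and
    adds a pooled lambda computed from the pooled statistics; ``type1`` holds
    pooled empirical type-I error over all null marker tests.
    """

    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame
    type1: pd.DataFrame
    n_replicates: int
    n_failed: int
    seeds: list


def simulate_structured_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a Balding-Nichols panel; returns (genotypes, subpopulation labels)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi, size=cfg.m)
    n_total = int(sum(cfg.n_per_subpop))
    calls = np.empty((n_total, cfg.m), dtype=np.int8)
    labels = np.empty(n_total, dtype=object)
    row = 0
    for size, name in zip(cfg.n_per_subpop, cfg.labels):
        if cfg.fst == 0:
            ps = p
        else:
            a = p * (1 - cfg.fst) / cfg.fst
            b = (1 - p) * (1 - cfg.fst) / cfg.fst
            ps = rng.beta(a, b)
        calls[row:row + size, :] = rng.binomial(2, ps, size=(size, cfg.m)).astype(np.int8)
        labels[row:row + size] = name
        row += size
    samples = [f"line{i:04d}" for i in range(n_total)]
    markers = [f"snp{j:05d}" for j in range(cfg.m)]
    chrom = np.array(["1"] * cfg.m, dtype=object)
    pos = np.arange(1, cfg.m + 1) * 100
    return GenotypeMatrix(samples, markers, chrom, pos, calls), labels


def simulate_binary_trait(labels, prevalence_map: dict, seed: int,
                          genotypes: GenotypeMatrix | None = None,
                          qtn_spec=None) -> np.ndarray:
    """Independent Bernoulli draws with subpopulation-specific prevalence.

    With the default ``qtn_spec=None`` there is no genetic component, so every
    marker is null by construction.  When QTN effects are given, they act
    additively on the log-odds scale around each subpopulation's baseline;
    each QTN's dosage is mean-centered so the stated prevalences remain the
    (approximate) realized trait prevalences.
    """
    labels = np.asarray(labels)
    missing = sorted(set(labels.tolist()) - set(prevalence_map))
    if missing:
        raise ValueError(f"no prevalence given for subpopulation(s) {missing}")
    rng = np.random.default_rng(seed)
    pi = np.array([prevalence_map[l] for l in labels], dtype=float)
    if qtn_spec:
        if genotypes is None:
            raise ValueError("genotypes required when planting QTN effects")
        eta = special.logit(np.clip(pi, 1e-12, 1 - 1e-12))
        for j, a in qtn_spec:
            x = genotypes.calls[:, j].astype(float)
            eta = eta + a * (x - x.mean())
        pi = special.expit(eta)
    return rng.binomial(1, pi).astype(float)


def simulate_quantitative_trait(G: GenotypeMatrix, labels, cfg: SimConfig) -> np.ndarray:
    """Additive QTN trait with optional structure-confounded shift.

    y = sum_j a_j x_j + c * 1[label == focal] + e, with the noise variance set
    so the QTN component explains the fraction ``cfg.h2`` of genetic + noise
    variance (focal = first configured label).
    """
    if not 0 <= cfg.h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed + 7)
    n = G.n_samples
    y_g = np.zeros(n)
    for j, a in cfg.qtn_spec:
        if not 0 <= j < G.n_markers:
            raise ValueError(f"QTN index {j} out of range")
        y_g = y_g + a * G.calls[:, j].astype(float)
    var_g = float(np.var(y_g))
    if cfg.h2 > 0 and var_g > 0:
        sigma2 = var_g * (1 - cfg.h2) / cfg.h2
    else:
        sigma2 = 1.0
    y = y_g + cfg.structure_effect * (labels == cfg.labels[0]).astype(float)
    return y + rng.normal(0.0, np.sqrt(sigma2), size=n)


def _replicate_diagnostics(y, G, X, K, strata, alphas):
    """One replicate: both GWAS runs, per-stratum lambdas, type-I error counts."""
    tables = {
        "LMM": lmm.run_lmm_gwas(y, G, X, K),
        "MLM": mlm.run_mlm_gwas(y, G, X, K),
    }
    report = diagnostics.stratified_diagnostics(tables["LMM"], tables["MLM"], strata)
    type1 = []
    for model, tab in tables.items():
        pv = tab.loc[tab["tested"], "p"].to_numpy()
        for a in alphas:
            type1.append({"model": model, "alpha": a,
                          "n_rejected": int((pv <= a).sum()), "n_tests": pv.size})
    stats_by_model = {m: tables[m].loc[tables[m]["tested"], ["marker", "stat", "p"]]
                      for m in tables}
    return report.table, pd.DataFrame(type1), stats_by_model


def type1_error_experiment(cfg: SimConfig, n_replicates: int,
                           alphas=(0.05, 0.01),
                           regenerate_genotypes: bool = False) -> ExperimentSummary:
    """The stratified null-trait experiment.

    One Balding-Nichols panel is drawn (held fixed across replicates by
    default), markers monomorphic within either subpopulation are removed, PCs
    and kinship are computed, and each replicate simulates a fresh null binary
    trait from ``cfg.prevalence_map`` (replicate r uses seed + r) and runs both
    GWAS models over all markers.  Per-stratum genomic-control lambdas and
    pooled empirical type-I error summarize how well each model controls false
    positives.  Replicate failures are recorded and tolerated as long as at
    least 80% succeed.
    """
    if len(cfg.n_per_subpop) != 2:
        raise ValueError("the stratified experiment requires exactly 2 subpopulations")

    def _prepare(seed):
        c = SimConfig(**{**cfg.__dict__, "seed": seed})
        G, labels = simulate_structured_genotypes(c)
        G, _removed = diagnostics.filter_monomorphic_within(G, labels)
        X = popstruct.compute_pcs(G, cfg.n_pcs)
        K = popstruct.compute_kinship(G)
        strata = diagnostics.variance_ratio_strata(G, labels, focal=cfg.labels[0])
        return G, labels, X, K, strata

    G, labels, X, K, strata = _prepare(cfg.seed)
    rep_rows, type1_rows, pooled = [], [], {}
    seeds, n_failed = [], 0
    for r in range(1, n_replicates + 1):
        seed_r = cfg.seed + r
        seeds.append(seed_r)
        try:
            if regenerate_genotypes and r > 1:
                G, labels, X, K, strata = _prepare(cfg.seed + 100000 + r)
            y = simulate_binary_trait(labels, cfg.prevalence_map, seed_r)
            rep_table, type1, stats_by_model = _replicate_diagnostics(
                y, G, X, K, strata, alphas)
        except Exception:  # noqa: BLE001 - replicate failures are recorded
            log.exception("replicate %d failed", r)
            n_failed += 1
            continue
        rep_table = rep_table.assign(replicate=r)
        rep_rows.append(rep_table)
        type1_rows.append(type1.assign(replicate=r))
        for model, df in stats_by_model.items():
            joined = df.merge(
                pd.DataFrame({"marker": strata.markers, "stratum": strata.stratum}),
                on="marker")
            pooled.setdefault(model, []).append(joined)
    if n_replicates and n_failed > 0.2 * n_replicates:
        raise RuntimeError(f"{n_failed}/{n_replicates} replicates failed")

    per_replicate = pd.concat(rep_rows, ignore_index=True)
    agg = (per_replicate.groupby(["model", "stratum"], as_index=False)
           .agg(lambda_mean=("lambda", "mean"), n_markers=("n_markers", "mean")))
    pooled_rows = []
    for model, parts in pooled.items():
        allp = pd.concat(parts, ignore_index=True)
        for name in ("all",) + diagnostics.STRATA:
            sub = allp if name == "all" else allp[allp["stratum"] == name]
            if sub.empty:
                continue
            lam = (diagnostics.genomic_control(sub["stat"].to_numpy()) if model == "LMM"
                   else diagnostics.genomic_control(p=sub["p"].to_numpy()))
            pooled_rows.append({"model": model, "stratum": name, "lambda_pooled": lam})
    agg = agg.merge(pd.DataFrame(pooled_rows), on=["model", "stratum"], how="left")

    type1_all = pd.concat(type1_rows, ignore_index=True)
    type1 = (type1_all.groupby(["model", "alpha"], as_index=False)
             .agg(n_rejected=("n_rejected", "sum"), n_tests=("n_tests", "sum")))
    type1["rate"] = type1["n_rejected"] / type1["n_tests"]
    return ExperimentSummary(per_replicate, agg, type1,
                             n_replicates - n_failed, n_failed, seeds)
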