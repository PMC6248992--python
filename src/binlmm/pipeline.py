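"""End-to-end orchestration: trait prep -> PCs/kinship -> GWAS -> diagnostics.

A run is described by a flat config (YAML mapping or :class:`RunConfig`); each
stage is skipped when a precomputed input is supplied.  Outputs are TSV files
plus a JSON manifest that echoes the resolved config, so a run can be
re-executed identically from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diagnostics, geno_io, lmm, mlm, popstruct, simulate, trait_prep

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (CLI flags mirror these keys)."""

    geno: str | None = None
    geno_format: str = "matrix"
    pheno: str | None = None
    trait: str | None = None
    percentile: float | None = None
    n_pcs: int = 3
    kinship_file: str | None = None
    covariates_file: str | None = None
    labels_file: str | None = None
    focal: str | None = None
    models: tuple[str, ...] = ("lmm", "mlm")
    fdr_levels: tuple[float, ...] = (0.05, 0.10)
    out_prefix: str = "run"
    seed: int = 0
    plots: bool = False
    sim: dict | None = None   # SimConfig fields; used when geno is None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("select at least one model")
        if any(not 0 < q < 1 for q in self.fdr_levels):
            raise ValueError("FDR levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "fdr_levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GWASReport:
    """In-memory result surface of one pipeline run."""

    tables: dict
    diagnostics_table: pd.DataFrame | None
    fdr_counts: pd.DataFrame
    manifest: dict
    files: list = field(default_factory=list)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("genotypes")
def _load_genotypes(cfg: RunConfig):
    if cfg.geno is not None:
        G = geno_io.read_genotypes(cfg.geno, cfg.geno_format)
        labels = None
        if cfg.labels_file:
            lab = pd.read_csv(cfg.labels_file, sep="\t", index_col=0)
            labels = lab.iloc[:, 0].reindex(G.samples).to_numpy(dtype=object)
        return geno_io.impute_major_allele(G), labels
    sim_cfg = simulate.SimConfig(**{**(cfg.sim or {}), "seed": cfg.seed})
    G, labels = simulate.simulate_structured_genotypes(sim_cfg)
    return G, labels


@_stage("phenotype")
def _load_trait(cfg: RunConfig, G, labels):
    if cfg.pheno is not None:
        df = trait_prep.read_phenotypes(cfg.pheno)
        if cfg.trait is None or cfg.trait not in df.columns:
            raise ValueError(f"trait {cfg.trait!r} not found in {cfg.pheno}")
        y = df[cfg.trait].reindex(G.samples)
    else:
        sim_cfg = simulate.SimConfig(**{**(cfg.sim or {}), "seed": cfg.seed})
        if sim_cfg.qtn_spec or sim_cfg.h2 > 0 or sim_cfg.structure_effect != 0:
            y = pd.Series(simulate.simulate_quantitative_trait(G, labels, sim_cfg),
                          index=G.samples, name="sim_quant")
        else:
            y = pd.Series(simulate.simulate_binary_trait(labels, sim_cfg.prevalence_map,
                                                         sim_cfg.seed + 1),
                          index=G.samples, name="sim_binary")
    if cfg.percentile is not None:
        y = trait_prep.dichotomize(y, cfg.percentile)
    return y


@_stage("structure")
def _structure(cfg: RunConfig, G):
    if cfg.covariates_file:
        X = popstruct.read_covariates(cfg.covariates_file)
        if list(X.samples) != list(G.samples):
            X_df = pd.DataFrame(X.design[:, 1:], index=X.samples)
            X_df = X_df.reindex(G.samples)
            X = popstruct.CovariateSet(list(G.samples),
                                       np.column_stack([np.ones(len(X_df)),
                                                        X_df.to_numpy()]),
                                       X.varexp)
    else:
        X = popstruct.compute_pcs(G, cfg.n_pcs)
    if cfg.kinship_file:
        K = popstruct.read_kinship(cfg.kinship_file)
        if list(K.samples) != list(G.samples):
            df = pd.DataFrame(K.values, index=K.samples, columns=K.samples)
            df = df.reindex(index=G.samples, columns=G.samples)
            K = popstruct.KinshipMatrix(list(G.samples), df.to_numpy())
    else:
        K = popstruct.compute_kinship(G)
    return X, K


def run_pipeline(cfg: RunConfig) -> GWASReport:
    """Execute the configured stages and write outputs under ``cfg.out_prefix``."""
    out_prefix = Path(cfg.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    try:
        G, labels = _load_genotypes(cfg)
        y = _load_trait(cfg, G, labels)
        keep = ~y.isna().to_numpy()
        if not keep.all():
            G = G.subset_samples(np.flatnonzero(keep))
            y = y[keep]
            if labels is not None:
                labels = np.asarray(labels)[keep]
        X, K = _structure(cfg, G)
        yv = y.to_numpy(dtype=float)

        tables: dict[str, pd.DataFrame] = {}
        if "lmm" in cfg.models:
            tables["LMM"] = lmm.run_lmm_gwas(yv, G, X, K, fdr_levels=cfg.fdr_levels)
        if "mlm" in cfg.models:
            tables["MLM"] = mlm.run_mlm_gwas(yv, G, X, K, fdr_levels=cfg.fdr_levels)

        diag_table = None
        fdr_rows = []
        if labels is not None and len(set(np.asarray(labels).tolist())) == 2 and \
                {"LMM", "MLM"} <= set(tables):
            focal = cfg.focal or str(np.asarray(labels)[0])
            Gf, _removed = diagnostics.filter_monomorphic_within(G, labels)
            strata = diagnostics.variance_ratio_strata(Gf, labels, focal)
            idx = [i for i, mk in enumerate(G.markers) if mk in set(Gf.markers)]
            sub = {m: tables[m].iloc[idx].reset_index(drop=True) for m in tables}
            report = diagnostics.stratified_diagnostics(sub["LMM"], sub["MLM"], strata,
                                                        cfg.fdr_levels)
            diag_table = report.table
            fdr_counts = report.fdr_counts
        else:
            for model, tab in tables.items():
                for q in cfg.fdr_levels:
                    col = f"fdr{int(round(q * 100)):02d}"
                    fdr_rows.append({"model": model, "q": q,
                                     "n_discoveries": int(tab[col].sum())})
            fdr_counts = pd.DataFrame(fdr_rows)

        for model, tab in tables.items():
            path = f"{out_prefix}.{model.lower()}.assoc.tsv"
            tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
            files.append(path)
            if cfg.plots:
                diagnostics.plot_manhattan(tab, f"{out_prefix}.{model.lower()}.manhattan.png")
        if diag_table is not None:
            path = f"{out_prefix}.diagnostics.tsv"
            diag_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            files.append(path)
        if cfg.plots and tables:
            diagnostics.plot_qq(tables, f"{out_prefix}.qq.png")

        manifest = {
            "package": "binlmm",
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "n_samples": G.n_samples,
            "n_markers": G.n_markers,
            "lambda_gc": {m: tables[m].attrs["lambda_gc"] for m in tables},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        mpath = f"{out_prefix}.manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2)
        files.append(mpath)
        return GWASReport(tables, diag_table, fdr_counts, manifest, files)
    except StageError:
        Path(f"{out_prefix}.failed").touch()
        raise
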