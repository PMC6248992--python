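"""Genotype input/output and additive coding.

Markers are held as an ``n_samples x n_markers`` matrix of additive codes
counting copies of the *minor* allele (0, 1, 2), with ``MISSING`` (-1) as the
sentinel for uncalled genotypes.  Three dialects are supported: VCF (biallelic
SNP GT fields, via cyvcf2), HapMap-style TSV (11 metadata columns followed by
one IUPAC single-letter diploid code per sample), and a plain numeric matrix
TSV whose codes are taken as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: IUPAC single-letter heterozygote codes for SNP alleles.
_IUPAC_HET = {"R", "Y", "S", "W", "K", "M"}

_HAPMAP_META_COLS = 11


class EmptyInputError(ValueError):
    """No markers survived parsing/filtering."""


class AllMissingMarkerError(ValueError):
    """A marker has no called genotypes, so its major allele is undefined."""


@dataclass
class GenotypeMatrix:
    """Additively coded genotype calls plus marker/sample metadata.

    Attributes
    ----------
    samples : list of str
        Unique sample identifiers (rows of ``calls``).
    markers : list of str
        Unique marker identifiers (columns of ``calls``).
    chrom : ndarray of object
        Chromosome label per marker.
    pos : ndarray of int
        1-based physical position (bp) per marker.
    calls : ndarray of int8, shape (n_samples, n_markers)
        Additive codes in {0, 1, 2}; ``MISSING`` marks uncalled cells.
    """

    samples: list[str]
    markers: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise ValueError("sample IDs do not match call-matrix rows")
        if not (len(self.markers) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("marker metadata does not match call-matrix columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs must be unique")
        if len(set(self.markers)) != m:
            raise ValueError("marker IDs must be unique")
        valid = (self.calls >= 0) & (self.calls <= 2)
        if not np.all(valid | (self.calls == MISSING)):
            raise ValueError("calls must be in {0,1,2} or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def has_missing(self) -> bool:
        return bool(np.any(self.calls == MISSING))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            list(self.markers),
            self.chrom.copy(),
            self.pos.copy(),
            self.calls.copy(),
        )

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples),
            [self.markers[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            self.calls[:, idx],
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            list(self.markers),
            self.chrom,
            self.pos,
            self.calls[idx, :],
        )


@dataclass
class AlleleFrequencyTable:
    """Per-marker counted-allele frequency and MAF.

    ``freq`` is the frequency of the counted (coded) allele among non-missing
    calls; ``maf = min(freq, 1 - freq)``.  ``subset`` records an optional
    sample-restriction label (e.g. a subpopulation name).
    """

    markers: list[str]
    freq: np.ndarray
    maf: np.ndarray = field(init=False)
    subset: str | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.maf = np.minimum(self.freq, 1.0 - self.freq)


def _orient_minor(dosage: np.ndarray, allele_a: str, allele_b: str) -> tuple[np.ndarray, str]:
    """Flip a counted-allele dosage column so it counts the minor allele.

    ``dosage`` counts ``allele_b``; ties (exact 0.5) are broken toward the
    lexicographically smaller allele symbol.  Returns the oriented column and
    the counted allele.
    """
    called = dosage != MISSING
    n_b = int(dosage[called].sum())
    n_tot = 2 * int(called.sum())
    if n_b * 2 > n_tot or (n_b * 2 == n_tot and allele_a < allele_b):
        out = dosage.copy()
        out[called] = 2 - out[called]
        return out, allele_a
    return dosage, allele_b


def read_genotypes(path: str, format: str) -> GenotypeMatrix:
    """Read genotypes from ``path`` under the named dialect.

    Parameters
    ----------
    path : str
        Input file.
    format : {"vcf", "hapmap", "matrix"}
        Dialect.  VCF and HapMap files are recoded to count the minor allele;
        numeric matrix files are taken as-is.

    Raises
    ------
    EmptyInputError
        If no biallelic SNP markers remain after parsing.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "matrix":
        return read_matrix(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, markers, chroms, poss = [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            log.warning("skipping multiallelic record %s:%d", var.CHROM, var.POS)
            continue
        dosage = np.full(len(samples), MISSING, dtype=np.int8)
        for j, (a0, a1, *_rest) in enumerate(var.genotypes):
            if a0 < 0 or a1 < 0:
                continue
            dosage[j] = (a0 == 1) + (a1 == 1)
        col, _counted = _orient_minor(dosage, str(var.REF), str(var.ALT[0]))
        cols.append(col)
        markers.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not cols:
        raise EmptyInputError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(samples, markers, np.array(chroms, dtype=object),
                          np.array(poss), np.column_stack(cols))


def _read_hapmap(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] <= _HAPMAP_META_COLS:
        raise EmptyInputError(f"no sample columns in HapMap file {path}")
    samples = list(df.columns[_HAPMAP_META_COLS:])
    cols, markers, chroms, poss = [], [], [], []
    for _, row in df.iterrows():
        alleles = str(row.iloc[1]).split("/")
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            log.warning("skipping non-biallelic-SNP HapMap row %s", row.iloc[0])
            continue
        a1, a2 = alleles
        dosage = np.full(len(samples), MISSING, dtype=np.int8)
        for j, code in enumerate(row.iloc[_HAPMAP_META_COLS:]):
            code = str(code).upper()
            if code == a2:
                dosage[j] = 2
            elif code == a1:
                dosage[j] = 0
            elif code in _IUPAC_HET:
                dosage[j] = 1
        col, _counted = _orient_minor(dosage, a1, a2)
        cols.append(col)
        markers.append(str(row.iloc[0]))
        chroms.append(str(row.iloc[2]))
        poss.append(int(row.iloc[3]))
    if not cols:
        raise EmptyInputError(f"no usable SNP rows in {path}")
    return GenotypeMatrix(samples, markers, np.array(chroms, dtype=object),
                          np.array(poss), np.column_stack(cols))


def read_matrix(path: str) -> GenotypeMatrix:
    """Read a numeric matrix TSV: marker ID column, optional chrom/pos, samples."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no markers in {path}")
    cols = list(df.columns)
    markers = df[cols[0]].astype(str).tolist()
    meta = {c.lower(): c for c in cols[1:3]}
    has_map = "chrom" in meta and "pos" in meta
    if has_map:
        chrom = df[meta["chrom"]].to_numpy(dtype=object)
        pos = df[meta["pos"]].astype(int).to_numpy()
        sample_cols = cols[3:]
    else:
        chrom = np.array(["0"] * len(markers), dtype=object)
        pos = np.arange(1, len(markers) + 1)
        sample_cols = cols[1:]
    if not sample_cols:
        raise EmptyInputError(f"no sample columns in {path}")
    vals = df[sample_cols].to_numpy()
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    called = ~pd.isna(vals) & (vals != "NA")
    calls[called] = vals[called].astype(float).astype(np.int8)
    return GenotypeMatrix(list(sample_cols), markers, chrom, pos, calls.T)


def write_matrix(G: GenotypeMatrix, path: str, include_map: bool = True) -> None:
    """Write the matrix-TSV dialect (inverse of :func:`read_matrix`)."""
    data: dict[str, object] = {"marker": G.markers}
    if include_map:
        data["chrom"] = G.chrom
        data["pos"] = G.pos
    body = G.calls.T.astype(object)
    body[body == MISSING] = "NA"
    for j, s in enumerate(G.samples):
        data[s] = body[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def allele_frequency(G: GenotypeMatrix, subset: np.ndarray | None = None,
                     label: str | None = None) -> AlleleFrequencyTable:
    """Counted-allele frequency (and MAF) per marker from non-missing calls.

    ``subset`` restricts to the given sample indices (must be non-empty).
    """
    calls = G.calls
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty sample subset")
        calls = calls[subset, :]
    called = calls != MISSING
    counts = np.where(called, calls, 0).sum(axis=0).astype(float)
    denom = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return AlleleFrequencyTable(list(G.markers), freq, subset=label)


def impute_major_allele(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the homozygous major-allele code per marker.

    The major allele is determined from non-missing calls at that marker; an
    exact tie (counted-allele frequency 0.5) imputes code 0, consistent with
    the minor-allele coding convention.  Idempotent.
    """
    out = G.copy()
    missing = out.calls == MISSING
    if not missing.any():
        return out
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = [G.markers[i] for i in np.flatnonzero(all_missing)]
        raise AllMissingMarkerError(f"markers with no called genotypes: {bad[:5]}")
    freq = allele_frequency(G).freq
    fill = np.where(freq > 0.5, 2, 0).astype(np.int8)
    out.calls = np.where(missing, fill[None, :], out.calls).astype(np.int8)
    return out
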