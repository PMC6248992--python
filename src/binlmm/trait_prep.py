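"""Phenotype loading and percentile dichotomization.

Quantitative traits are pandas Series (or float arrays) aligned to sample IDs
with NaN for missing; binary traits are 0/1 floats with NaN preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype TSV: first column sample ID, one column per trait, NA missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df


def dichotomize(y, percentile: float):
    """Binarize a quantitative trait at a percentile of its non-missing values.

    The threshold is the linear-interpolation quantile of the non-missing
    values; samples strictly greater than the threshold become 1, the rest 0,
    and missing values stay missing.  A constant trait yields all zeros (no
    value exceeds its own percentile) with a logged warning.

    Parameters
    ----------
    y : pandas Series or 1-d array of float
    percentile : float in (0, 100)

    Returns
    -------
    Same container type as ``y`` with values in {0.0, 1.0, NaN}.  For Series
    the percentile is recorded in ``result.attrs["percentile"]``.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    values = np.asarray(y, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values to dichotomize")
    if np.all(obs == obs[0]):
        log.warning("constant trait: dichotomization yields all zeros")
    t = np.percentile(obs, percentile)  # linear interpolation ("type 7")
    out = np.where(np.isnan(values), np.nan, (values > t).astype(float))
    if isinstance(y, pd.Series):
        s = pd.Series(out, index=y.index, name=y.name)
        s.attrs["percentile"] = percentile
        s.attrs["threshold"] = float(t)
        return s
    return out
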