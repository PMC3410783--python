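"""Normalization and filtering of the log2 mRNA expression matrix.

Quantile normalization equalizes the across-sample intensity
distributions (the distribution-matching core of RMA-style array
preprocessing); the low-expression filter drops probes that never rise
above a log2 floor in any sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["quantile_normalize", "low_expression_filter"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the sorted columns.

    After normalization each column's sorted values equal the reference
    distribution (the across-column mean of order statistics), so all
    column means, medians and quantiles coincide.  Ties within a column
    receive the mean of the reference values at the tied ranks, which
    makes the procedure deterministic and idempotent.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 columns; returning input unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = reference
        # ties: average the reference values assigned to equal inputs
        s = pd.Series(ranked)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def low_expression_filter(matrix: pd.DataFrame, min_log2: float = 5.0) -> pd.DataFrame:
    """Keep probes whose maximum across samples reaches ``min_log2``.

    Operationalizes "low expression at all time points" as a max-based
    rule: a probe is uninformative only if it stays below the floor in
    every sample.  Raises if nothing survives, since downstream
    statistics are undefined on an empty matrix.
    """
    keep = matrix.max(axis=1) >= min_log2
    if not keep.any():
        raise ValueError(f"low-expression filter at {min_log2} removed every probe")
    return matrix.loc[keep]
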