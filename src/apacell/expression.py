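"""3' UTR-level expression from peak counts: per-UTR sums, CPM, quantile
normalization across clusters."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counting import PeakCountMatrix, cpm


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common target distribution.

    The target is the row-wise mean of the column-sorted values; ties are
    handled by averaging ranks and linearly interpolating the target at
    fractional ranks. After normalization every column has the same sorted
    value multiset (exactly, absent ties).
    """
    vals = df.values.astype(float)
    n = vals.shape[0]
    if n == 0:
        return df.copy()
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    ranks = df.rank(method="average").values  # 1-based, fractional on ties
    for j in range(vals.shape[1]):
        out[:, j] = np.interp(ranks[:, j], np.arange(1, n + 1), target)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def utr_expression(matrix: PeakCountMatrix) -> pd.DataFrame:
    """UTR x cluster expression: peak counts summed per UTR, CPM-normalized
    per cluster, then quantile-normalized across clusters."""
    summed = matrix.counts.groupby(matrix.peaks["region_id"]).sum()
    summed.index.name = "utr_id"
    return quantile_normalize(cpm(summed))
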