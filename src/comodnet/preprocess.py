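"""Array preprocessing: quantile normalization, flag handling, replicate collapse.

The stage order mirrors single-channel array practice: between-array quantile
normalization of raw intensities, zero-weighting of flagged spots, a
per-feature median over the (unflagged) replicate spots, then a log2
transform. Background subtraction is deliberately absent. A feature whose
replicates are all flagged in a sample becomes missing; features missing in
more than a configurable fraction of samples are dropped before network
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, TransformError
from .matrix import ExpressionMatrix

#: default missingness threshold above which a feature is dropped
MAX_MISSING_FRACTION = 0.25


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    After normalization every sample column, when sorted, equals the
    across-sample mean of the sorted columns; within-column rank order is
    preserved. Tied values within a column receive the mean of the reference
    values at their tied ranks.
    """
    if m.n_samples < 2:
        raise NormalizationError("quantile normalization needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise NormalizationError("missing values not allowed before normalization")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties within a column share the mean reference value of their ranks
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


def remove_flagged(m: ExpressionMatrix, flags: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Zero-weight flagged spot x sample entries; drop fully flagged spot rows.

    Flagged entries are kept as NaN in the returned matrix's ``flags`` mask so
    downstream medians exclude them. ``flags`` overrides the matrix's own
    flags if given.
    """
    if flags is None:
        flags = m.flags
    if flags is None:
        return m
    if flags.shape != m.values.shape:
        raise InputError("flags shape does not match matrix shape")
    flags = flags.astype(bool)
    flags.index = m.values.index
    flags.columns = m.values.columns
    keep = ~flags.all(axis=1)
    values = m.values.loc[keep]
    flags = flags.loc[keep]
    rep_map = m.replicate_map.loc[values.index] if m.replicate_map is not None else None
    return ExpressionMatrix(values=values, scale=m.scale, flags=flags, replicate_map=rep_map)


def collapse_replicates(
    m: ExpressionMatrix, replicate_map: pd.Series | None = None
) -> ExpressionMatrix:
    """Collapse replicate spots to one row per feature by the unflagged median.

    A feature with zero unflagged replicates in a sample gets a missing value
    (NaN); use :func:`drop_missing_features` before correlation-based stages.
    """
    if replicate_map is None:
        replicate_map = m.replicate_map
    if replicate_map is None:
        raise InputError("no replicate map available")
    missing = set(m.values.index) - set(replicate_map.index)
    if missing:
        raise InputError(f"spots not in replicate map: {sorted(missing)[:5]}")
    values = m.values.to_numpy(dtype=float).copy()
    if m.flags is not None:
        values[m.flags.to_numpy()] = np.nan
    df = pd.DataFrame(values, index=m.values.index, columns=m.values.columns)
    feats = replicate_map.loc[df.index]
    collapsed = df.groupby(feats.to_numpy()).median()
    # preserve first-appearance feature order rather than groupby's sort order
    order = list(dict.fromkeys(feats))
    collapsed = collapsed.loc[order]
    collapsed.index.name = m.values.index.name
    return ExpressionMatrix(values=collapsed, scale=m.scale)


def drop_missing_features(
    m: ExpressionMatrix, max_missing_fraction: float = MAX_MISSING_FRACTION
) -> ExpressionMatrix:
    """Drop features missing in more than ``max_missing_fraction`` of samples."""
    frac = m.values.isna().mean(axis=1)
    return m.with_values(m.values.loc[frac <= max_missing_fraction])


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform an intensity-scale matrix; guard against re-application."""
    if m.scale != "intensity":
        raise TransformError("data are already on the log2 scale")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise TransformError("log2 transform requires strictly positive values")
    return m.with_values(np.log2(m.values), scale="log2")


def preprocess_pipeline(
    m: ExpressionMatrix, max_missing_fraction: float = MAX_MISSING_FRACTION
) -> ExpressionMatrix:
    """Full preprocessing for a raw replicate-spot intensity matrix.

    quantile normalization -> flag removal -> replicate median -> log2 ->
    missingness filter. A matrix already on the log2 scale without replicates
    (e.g. standardized gel-spot abundances) passes through the applicable
    steps only.
    """
    if m.scale == "intensity":
        m = quantile_normalize(m)
    m = remove_flagged(m)
    if m.replicate_map is not None:
        m = collapse_replicates(m)
    if m.scale == "intensity":
        m = log2_transform(m)
    return drop_missing_features(m, max_missing_fraction)
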