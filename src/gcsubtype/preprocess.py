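"""Expression normalization and gene filtering.

Quantile normalization forces every sample onto the common distribution of
across-sample order-statistic means (ties mapped to the mean of their tied
target values); the variable-gene filter keeps genes showing at least a
``fold``-fold deviation from their own median in at least ``min_samples``
samples, the standard pre-clustering feature selection for two-color-style
log2 displays.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError


def drop_missing_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with any missing value (the package's missing-data policy)."""
    keep = matrix.values.notna().all(axis=1)
    return matrix.with_values(matrix.values.loc[keep])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Make every sample's value distribution identical.

    Each sample's sorted vector becomes the across-sample mean of order
    statistics; within-sample ranks are preserved, with ties assigned the
    mean of the tied ranks' target values.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if matrix.values.isna().any().any():
        raise ValidationError(
            "missing values present: impute or drop_missing_genes first"
        )
    vals = matrix.values.to_numpy(float)
    target = np.sort(vals, axis=0).mean(axis=1)
    ranks = matrix.values.rank(axis=0, method="average").to_numpy(float)
    out = np.interp(ranks - 1.0, np.arange(vals.shape[0]), target)
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    if matrix.scale == "log2":
        raise ValidationError("matrix already on log2 scale; refusing double transform")
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    shifted = matrix.values + offset
    if (shifted <= 0).any().any():
        raise ValidationError("non-positive values after offset; cannot take log2")
    return matrix.with_values(np.log2(shifted), scale="log2")


def linear_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform` at offset 0."""
    if matrix.scale == "linear":
        raise ValidationError("matrix already on linear scale")
    return matrix.with_values(np.exp2(matrix.values), scale="linear")


def filter_variable_genes(matrix: ExpressionMatrix, fold: float = 2.0,
                          min_samples: int = 15) -> ExpressionMatrix:
    """Keep genes with >= fold-fold deviation from their median in
    >= ``min_samples`` samples (both bounds inclusive), log2 scale."""
    if matrix.scale != "log2":
        raise ValidationError("variable-gene filter expects log2-scale data")
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    if min_samples > matrix.n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds n_samples={matrix.n_samples}; "
            "no gene can pass, returning empty matrix"
        )
    threshold = np.log2(fold)
    dev = matrix.values.sub(matrix.values.median(axis=1), axis=0).abs()
    keep = (dev >= threshold).sum(axis=1) >= min_samples
    return matrix.with_values(matrix.values.loc[keep])


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.scale != "log2":
        raise ValidationError("median centering expects log2-scale data")
    return matrix.with_values(
        matrix.values.sub(matrix.values.median(axis=1), axis=0)
    )
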