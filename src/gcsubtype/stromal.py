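"""Tumor-fraction estimation and stromal-contribution adjustment.

Bulk tumor expression is modeled on the linear scale as a two-component
mixture ``observed ~ p * tumor_ref + (1 - p) * normal_ref`` with tumor
fraction ``p``.  With exactly two reference profiles the least-squares
fraction has a closed form, which this module uses (clipped to [0, 1]) —
a deliberately simple, identifiable two-reference estimator.

Two adjustment modes are shipped: ``as_published`` multiplies linear-scale
expression by the tumor fraction (the literal published rule, which scales
rather than removes the stromal component), and ``model_based`` inverts
the mixture, ``(observed - (1 - p) * normal_ref) / p``, floored at zero.
The discrepancy between the two is documented, not resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

MIN_SHARED_GENES = 10
MIN_FRACTION_FOR_INVERSION = 0.05
_LINEAR_FLOOR = 1e-6


@dataclass
class DeconvolutionResult:
    tumor_fraction: pd.Series
    residual_norm: pd.Series

    def to_tsv(self, path) -> None:
        self.tumor_fraction.rename("tumor_fraction").rename_axis("sample_id") \
            .to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DeconvolutionResult":
        frac = pd.read_csv(path, sep="\t", index_col="sample_id")["tumor_fraction"]
        return cls(tumor_fraction=frac,
                   residual_norm=pd.Series(np.nan, index=frac.index))


def _as_linear_profile(profile: pd.Series, scale: str) -> pd.Series:
    if scale == "linear":
        return profile.astype(float)
    if scale == "log2":
        return np.exp2(profile.astype(float))
    raise ValidationError("reference scale must be 'linear' or 'log2'")


def reference_profiles(matrix: ExpressionMatrix):
    """Mean linear-scale tumor and normal profiles from an annotated matrix."""
    lin = matrix.to_linear()
    tumors = lin.samples_of_type("tumor")
    normals = lin.samples_of_type("normal")
    if not tumors or not normals:
        raise ValidationError("need both tumor and normal samples for references")
    return lin.values[tumors].mean(axis=1), lin.values[normals].mean(axis=1)


def estimate_tumor_fraction(matrix: ExpressionMatrix, tumor_ref: pd.Series,
                            normal_ref: pd.Series,
                            ref_scale: str = "linear") -> DeconvolutionResult:
    """Closed-form constrained least-squares tumor fraction per sample.

    p = <y - n, t - n> / ||t - n||^2 over shared genes, clipped to [0, 1].
    """
    t = _as_linear_profile(tumor_ref, ref_scale)
    n = _as_linear_profile(normal_ref, ref_scale)
    shared = matrix.gene_ids.intersection(t.index).intersection(n.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} genes shared with references (need >= {MIN_SHARED_GENES})"
        )
    t = t.loc[shared].to_numpy()
    n = n.loc[shared].to_numpy()
    d = t - n
    denom = float(d @ d)
    if denom == 0.0 or np.allclose(t, n):
        raise ValidationError("tumor and normal references coincide: unidentifiable")
    y = matrix.to_linear().values.loc[shared].to_numpy(float)
    p = np.clip(((y - n[:, None]) * d[:, None]).sum(axis=0) / denom, 0.0, 1.0)
    fitted = p[None, :] * t[:, None] + (1 - p)[None, :] * n[:, None]
    residual = np.linalg.norm(y - fitted, axis=0)
    return DeconvolutionResult(
        tumor_fraction=pd.Series(p, index=matrix.sample_ids, name="tumor_fraction"),
        residual_norm=pd.Series(residual, index=matrix.sample_ids, name="residual_norm"),
    )


def adjust_expression(matrix: ExpressionMatrix, fractions: DeconvolutionResult,
                      mode: str = "as_published",
                      normal_ref: pd.Series | None = None,
                      ref_scale: str = "linear") -> ExpressionMatrix:
    """Remove (or rescale away) the stromal contribution; returns log2 scale.

    ``model_based`` requires ``normal_ref`` and flags samples with tumor
    fraction below 5%, which are returned unadjusted (inversion there is
    numerically meaningless).
    """
    p = fractions.tumor_fraction.reindex(matrix.sample_ids)
    if p.isna().any():
        raise ValidationError("tumor fraction missing for some samples")
    lin = matrix.to_linear().values
    if mode == "as_published":
        adj = lin.mul(p, axis=1)
    elif mode == "model_based":
        if normal_ref is None:
            raise ValidationError("model_based adjustment requires normal_ref")
        n = _as_linear_profile(normal_ref, ref_scale).reindex(matrix.gene_ids)
        if n.isna().any():
            raise ValidationError("normal_ref missing genes of the matrix")
        low = p < MIN_FRACTION_FOR_INVERSION
        if low.any():
            warnings.warn(
                f"{int(low.sum())} samples with tumor fraction < "
                f"{MIN_FRACTION_FOR_INVERSION} left unadjusted"
            )
        safe_p = p.where(~low, 1.0)
        adj = (lin.sub(np.outer(n, (1 - safe_p)), axis=0)).div(safe_p, axis=1)
        adj = adj.clip(lower=0.0)
        adj.loc[:, low] = lin.loc[:, low]
    else:
        raise ValidationError("mode must be 'as_published' or 'model_based'")
    return matrix.with_values(np.log2(adj.clip(lower=_LINEAR_FLOOR)), scale="log2")
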