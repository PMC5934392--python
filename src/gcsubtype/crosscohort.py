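"""Cross-cohort conserved-gene selection and companion genomic contrasts.

A gene is conserved subtype-specific when its MP-vs-EP two-sample t test
is significant at ``p_cutoff`` in every cohort with the same direction of
change in every cohort (direction consistency is configurable).  Ratio
ranking orders genes by the across-cohort mean MP-EP log2 difference.
Methylation-expression coupling is quantified by per-gene Pearson
correlation, and hypermutated tumors are called by a strict
mutations-per-megabase threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EP, MP, ExpressionMatrix, SubtypeLabels, ValidationError
from .discovery import two_sample_ttest


@dataclass
class CohortSet:
    """Cohort-id keyed (ExpressionMatrix, SubtypeLabels) pairs."""

    cohorts: dict

    def __post_init__(self) -> None:
        if len(self.cohorts) < 2:
            raise ValidationError("CohortSet needs >= 2 cohorts")
        for cid, (matrix, labels) in self.cohorts.items():
            if not labels.samples(MP) or not labels.samples(EP):
                raise ValidationError(f"cohort {cid!r} lacks one of the subtypes")

    def items(self):
        return self.cohorts.items()

    def __len__(self) -> int:
        return len(self.cohorts)


def _harmonized_universe(cohorts: CohortSet) -> pd.Index:
    """Shared gene universe after uppercasing symbols; duplicates dropped."""
    universe = None
    for cid, (matrix, _) in cohorts.items():
        ids = pd.Index([str(g).upper() for g in matrix.gene_ids])
        ids = ids[~ids.duplicated()]
        universe = ids if universe is None else universe.intersection(ids)
    if universe is None or len(universe) == 0:
        raise ValidationError("empty shared gene universe across cohorts")
    return universe


def _uppercased(matrix: ExpressionMatrix, universe: pd.Index) -> ExpressionMatrix:
    values = matrix.values.copy()
    values.index = pd.Index([str(g).upper() for g in values.index])
    values = values.loc[~values.index.duplicated()]
    return ExpressionMatrix(values.loc[universe], matrix.sample_annotations,
                            scale=matrix.scale)


def conserved_genes(cohorts: CohortSet, p_cutoff: float = 0.001,
                    require_direction: bool = True) -> pd.DataFrame:
    """Per-gene per-cohort stats plus the conserved membership flag.

    Returns a DataFrame indexed by gene with ``t_<cohort>``, ``p_<cohort>``
    columns, the shared direction, and a boolean ``conserved`` column:
    significant in every cohort and (if ``require_direction``) with an
    identical MP-EP sign in every cohort.
    """
    universe = _harmonized_universe(cohorts)
    per_cohort = {}
    for cid, (matrix, labels) in cohorts.items():
        mat = _uppercased(matrix, universe)
        per_cohort[cid] = two_sample_ttest(mat, labels.samples(MP), labels.samples(EP))

    out = pd.DataFrame(index=universe)
    sig_all = pd.Series(True, index=universe)
    signs = []
    for cid, res in per_cohort.items():
        out[f"t_{cid}"] = res["t"]
        out[f"p_{cid}"] = res["p"]
        sig_all &= res["p"] < p_cutoff
        signs.append(np.sign(res["mean_diff"]))
    signs = pd.concat(signs, axis=1)
    same_dir = signs.nunique(axis=1).eq(1) & signs.iloc[:, 0].ne(0)
    out["direction"] = signs.iloc[:, 0].where(same_dir, 0).astype(int)
    out["conserved"] = sig_all & (same_dir if require_direction else True)
    return out


def rank_by_ratio(genes, cohorts: CohortSet) -> pd.DataFrame:
    """Rank genes by across-cohort mean MP-EP log2 difference, descending.

    Ties are broken lexicographically by gene id; ranking is invariant to
    cohort order (a plain mean over cohorts).
    """
    genes = pd.Index([str(g).upper() for g in genes])
    universe = _harmonized_universe(cohorts)
    missing = genes.difference(universe)
    if len(missing):
        raise ValidationError(f"genes outside shared universe: {list(missing)[:5]}")
    diffs = {}
    for cid, (matrix, labels) in cohorts.items():
        mat = _uppercased(matrix, universe)
        mp = mat.values[labels.samples(MP)].mean(axis=1)
        ep = mat.values[labels.samples(EP)].mean(axis=1)
        diffs[cid] = (mp - ep).loc[genes]
    table = pd.DataFrame(diffs)
    table["mean_log2_ratio"] = table.mean(axis=1)
    table = (
        table.assign(_gene=table.index)
        .sort_values(["mean_log2_ratio", "_gene"], ascending=[False, True])
        .drop(columns="_gene")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def methylation_expression_correlation(expr: ExpressionMatrix, meth: pd.DataFrame,
                                       genes=None) -> pd.DataFrame:
    """Per-gene Pearson r between promoter beta-value and log2 expression.

    Two-sided p via the exact t transform; genes with < 3 shared samples or
    zero variance in either vector are reported with NaN and flagged.
    """
    if genes is None:
        genes = meth.index.intersection(expr.gene_ids)
    genes = list(genes)
    shared = meth.columns.intersection(expr.sample_ids)
    rows = []
    for g in genes:
        if g not in expr.gene_ids.values or g not in meth.index:
            raise ValidationError(f"gene {g!r} missing from expression or methylation")
        x = expr.values.loc[g, shared].to_numpy(float)
        y = meth.loc[g, shared].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            rows.append({"gene_id": g, "r": np.nan, "p": np.nan, "n": len(x),
                         "flag": "fewer than 3 shared samples"})
            continue
        if x.std() == 0 or y.std() == 0:
            rows.append({"gene_id": g, "r": np.nan, "p": np.nan, "n": len(x),
                         "flag": "zero variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene_id": g, "r": float(r), "p": float(p), "n": len(x),
                     "flag": ""})
    return pd.DataFrame(rows).set_index("gene_id")


HYPERMUTATION_THRESHOLD = 11.4   # mutations/Mb; strictly greater => hypermutated


def classify_hypermutated(rates: pd.Series,
                          threshold: float = HYPERMUTATION_THRESHOLD) -> pd.Series:
    """Strictly-greater-than threshold call on mutations/Mb."""
    rates = pd.Series(rates, dtype=float)
    if (rates < 0).any():
        raise ValidationError("negative mutation rates")
    return pd.Series(
        np.where(rates > threshold, "hypermutated", "non-hypermutated"),
        index=rates.index,
        name="hypermutation",
    )


def compare_mutation_rates(rates: pd.Series, labels: SubtypeLabels,
                           log_scale: bool = False):
    """Two-sided Student's t-test of MP vs EP mutation rates -> (t, p)."""
    rates = rates.reindex(labels.sample_ids).astype(float)
    if rates.isna().any():
        raise ValidationError("mutation rates missing for some labeled samples")
    mp = rates.loc[labels.samples(MP)].to_numpy()
    ep = rates.loc[labels.samples(EP)].to_numpy()
    if len(mp) == 0 or len(ep) == 0:
        raise ValidationError("one subtype absent from mutation-rate comparison")
    if log_scale:
        if (rates <= 0).any():
            raise ValidationError("log-scale comparison requires positive rates")
        mp, ep = np.log10(mp), np.log10(ep)
    t, p = stats.ttest_ind(mp, ep, equal_var=True)
    return float(t), float(p)
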