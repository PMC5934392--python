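"""Unsupervised subtype discovery and signature derivation.

Two-cluster agglomerative clustering (centered Pearson correlation
distance, average linkage) splits tumors into a small mesenchymal-like
cluster (MP) and a large epithelial-like cluster (EP).  The signature is
the intersection of two independent differential-expression lists — MP vs
EP and MP vs non-tumor mucosa, each at a raw two-sample t-test
``p < p_cutoff`` — further restricted to genes with at least a
``fold``-fold MP-vs-EP mean difference; weights are the MP-vs-EP
t statistics (positive = MP-high).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import (
    EP,
    MP,
    ExpressionMatrix,
    GeneSignature,
    SubtypeLabels,
    ValidationError,
)


def hierarchical_cluster(matrix: ExpressionMatrix, k: int = 2,
                         metric: str = "correlation", method: str = "average",
                         include_outgroup: bool = True) -> SubtypeLabels:
    """Cluster samples and name the smaller tumor cluster MP.

    Outgroup samples (if present and ``include_outgroup``) co-cluster but
    receive no subtype label; cluster sizes for the small/large naming are
    counted over tumor samples only.  An exact size tie is broken by
    assigning MP to the cluster containing the lexicographically smallest
    tumor sample id.
    """
    if k != 2:
        raise ValidationError("subtype naming is defined for k=2 only")
    ann = matrix.sample_annotations
    use = [s for s in matrix.sample_ids
           if ann.loc[s, "tissue_type"] == "tumor"
           or (include_outgroup and ann.loc[s, "tissue_type"] == "outgroup")]
    if k > len(use):
        raise ValidationError(f"k={k} exceeds number of clusterable samples ({len(use)})")
    sub = matrix.subset_samples(use)
    X = sub.values.to_numpy(float).T          # samples x genes
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    assignment = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignment = pd.Series(assignment, index=sub.sample_ids)

    tumor_ids = [s for s in use if ann.loc[s, "tissue_type"] == "tumor"]
    tumor_assign = assignment.loc[tumor_ids]
    counts = tumor_assign.value_counts()
    if len(counts) == 1:
        # degenerate cut: every tumor in one cluster
        small = counts.index[0]
    elif counts.iloc[0] == counts.iloc[1]:
        small = tumor_assign.loc[min(tumor_ids)]
    else:
        small = counts.idxmin()
    labels = pd.Series(
        np.where(tumor_assign == small, MP, EP), index=tumor_ids, name="subtype"
    )
    return SubtypeLabels(labels)


def linkage_newick(matrix: ExpressionMatrix, metric: str = "correlation",
                   method: str = "average") -> str:
    """Newick export of the sample dendrogram, for inspection."""
    X = matrix.values.to_numpy(float).T
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    tree = hierarchy.to_tree(Z)
    names = list(matrix.sample_ids)

    def walk(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def two_sample_ttest(matrix: ExpressionMatrix, group_a, group_b,
                     equal_var: bool = True) -> pd.DataFrame:
    """Per-gene two-sided t test between two sample groups.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``,
    ``mean_diff`` (a minus b) and ``degenerate`` (zero pooled variance,
    reported as t=0, p=1).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    a = matrix.values[group_a].to_numpy(float)
    b = matrix.values[group_b].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"t": t, "p": p, "mean_diff": a.mean(axis=1) - b.mean(axis=1),
         "degenerate": degenerate},
        index=matrix.gene_ids,
    )


def derive_signature(matrix: ExpressionMatrix, clusters: SubtypeLabels,
                     normal_samples, p_cutoff: float = 0.001, fold: float = 2.0,
                     fold_scale: str = "log2") -> GeneSignature:
    """Two-list signature: (MP vs EP) ∩ (MP vs normals), then fold filter.

    ``fold_scale`` selects whether the fold-change filter compares means of
    log2 values ("log2", the default) or log-ratios of linear-scale means
    ("linear"); both operate on the MP-vs-EP contrast.
    """
    normal_samples = list(normal_samples)
    mp = clusters.samples(MP)
    ep = clusters.samples(EP)
    if set(normal_samples) & set(clusters.sample_ids):
        raise ValidationError("normal samples must be disjoint from clustered tumors")
    x = two_sample_ttest(matrix, mp, ep)
    y = two_sample_ttest(matrix, mp, normal_samples)
    in_x = x["p"] < p_cutoff
    in_y = y["p"] < p_cutoff

    if fold_scale == "log2":
        lfc = x["mean_diff"]
    elif fold_scale == "linear":
        lin = np.exp2(matrix.values)
        lfc = np.log2(lin[mp].mean(axis=1) / lin[ep].mean(axis=1))
    else:
        raise ValidationError("fold_scale must be 'log2' or 'linear'")
    passes_fold = lfc.abs() >= np.log2(fold)

    keep = in_x & in_y & passes_fold
    if not keep.any():
        warnings.warn("empty signature: no gene passed both lists and the fold filter")
    table = pd.DataFrame(
        {
            "weight": x.loc[keep, "t"],
            "log2_fold_change": lfc[keep],
            "p_value": x.loc[keep, "p"],
        }
    )
    table.index.name = "gene_id"
    return GeneSignature(table)
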