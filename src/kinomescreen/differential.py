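"""Differential kinase activity and exploratory structure.

With only a handful of organoid lines per group, formal per-kinase tests are
underpowered; group contrasts are therefore reported as fold changes against
a threshold (default > 2), alongside a global Kruskal-Wallis test across
samples, PCA of the activity matrix, Pearson-distance hierarchical
clustering, and a three-way classification of peptides into
high / heterogeneous / low phosphorylation classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "fold_change",
    "kinase_fold_change",
    "kruskal_wallis_samples",
    "pca_samples",
    "hierarchical_cluster",
    "classify_peptides",
]


def _group_means(matrix: pd.DataFrame, samples: list[str]) -> pd.Series:
    if not samples:
        raise ValueError("empty sample group")
    missing = [s for s in samples if s not in matrix.index]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    return matrix.loc[samples].mean(axis=0)


def _fc_records(
    ratio: pd.Series,
    label_a: str,
    label_b: str,
    threshold: float,
    support: pd.Series | None,
) -> pd.DataFrame:
    hi_is_a = ratio >= 1.0
    out = pd.DataFrame(
        {
            "feature": ratio.index,
            "fold_change": np.where(hi_is_a, ratio, 1.0 / ratio),
            "group_hi": np.where(hi_is_a, label_a, label_b),
            "group_lo": np.where(hi_is_a, label_b, label_a),
        }
    )
    if support is not None:
        out["n_peptides"] = support.reindex(ratio.index).to_numpy()
    out["above_threshold"] = out["fold_change"] > threshold
    return out.sort_values(
        ["fold_change", "feature"], ascending=[False, True], ignore_index=True
    )


def fold_change(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    threshold: float = 2.0,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-feature fold change between two sample groups.

    FC is the ratio of group means, reported as a max/min ratio >= 1 with the
    higher group named in ``group_hi``. Features are returned sorted by fold
    change (descending) with an ``above_threshold`` flag (strict >).
    Values must be strictly positive (guaranteed upstream by zero
    replacement).
    """
    mean_a = _group_means(matrix, group_a)
    mean_b = _group_means(matrix, group_b)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError("fold change requires strictly positive group means")
    return _fc_records(mean_a / mean_b, label_a, label_b, threshold, None)


def kinase_fold_change(
    peptide_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    threshold: float = 2.0,
    label_a: str = "A",
    label_b: str = "B",
    agg: str = "arithmetic",
) -> pd.DataFrame:
    """Average fold change per upstream kinase over its member peptides.

    Each member peptide contributes its signed ratio mean(A)/mean(B); the
    kinase-level value is the arithmetic (default) or geometric mean of those
    ratios, with the direction resolved after averaging.
    """
    if agg not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown aggregation {agg!r}")
    mean_a = _group_means(peptide_matrix, group_a)
    mean_b = _group_means(peptide_matrix, group_b)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError("fold change requires strictly positive group means")
    ratio = mean_a / mean_b
    present = annotation[annotation["peptide_id"].isin(peptide_matrix.columns)]
    groups = present.groupby("kinase")["peptide_id"].apply(list)
    agg_ratio, support = {}, {}
    for kin in sorted(groups.index):
        r = ratio[groups[kin]].to_numpy()
        agg_ratio[kin] = float(np.exp(np.log(r).mean())) if agg == "geometric" else float(r.mean())
        support[kin] = len(r)
    return _fc_records(
        pd.Series(agg_ratio), label_a, label_b, threshold, pd.Series(support)
    )


def kruskal_wallis_samples(matrix: pd.DataFrame) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test treating each sample's peptide vector as a group.

    Returns the tie-corrected H statistic and its chi-square p-value
    (df = n_samples - 1). An all-tied input yields H = 0, p = 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    groups = [matrix.loc[s].dropna().to_numpy() for s in matrix.index]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every sample needs at least one value")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pca_samples(
    matrix: pd.DataFrame, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the samples x features activity matrix.

    Features are mean-centered (and unit-scaled when ``scale``); components
    come from the SVD with a deterministic sign convention (the
    largest-magnitude feature loading of each component is positive).

    Returns (sample coordinates, explained-variance ratios summing to 1,
    feature loadings).
    """
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("activity matrix has rank 0 after centering")
    for j in range(vt.shape[0]):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    coords = u * s
    evr = s**2 / (s**2).sum()
    pcs = [f"PC{j + 1}" for j in range(len(s))]
    return (
        pd.DataFrame(coords, index=matrix.index, columns=pcs),
        evr,
        pd.DataFrame(vt.T, index=matrix.columns, columns=pcs),
    )


def pearson_distance(vectors: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between the rows; zero-variance rows get distance 1."""
    v = vectors.to_numpy(dtype=float)
    sd = v.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance vector(s); their correlation "
            "distances set to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v)
    d = 1.0 - r
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    return pd.DataFrame(d, index=vectors.index, columns=vectors.index)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    transform: str | None = "log10",
    axis: str = "samples",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering on 1 - Pearson correlation distance.

    ``axis="samples"`` clusters rows, ``axis="features"`` clusters columns.
    ``transform`` may be "log10" (requires a positive matrix), "zscore"
    (per-feature, across samples) or None. Labels are sorted before distance
    computation so leaf order is deterministic under input permutation.

    Returns the scipy linkage matrix and the leaf labels in dendrogram order.
    """
    data = matrix
    if transform == "log10":
        if (data.to_numpy() <= 0).any():
            raise ValueError("log10 transform requires a strictly positive matrix")
        data = np.log10(data)
    elif transform == "zscore":
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1).replace(0.0, 1.0)
        data = data.sub(mean, axis=1).div(sd, axis=1)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    if axis == "features":
        data = data.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    data = data.sort_index()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 vectors to cluster")
    dist = pearson_distance(data)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=method)
    order = [data.index[i] for i in leaves_list(z)]
    return z, order


def classify_peptides(
    matrix: pd.DataFrame, k: int = 3, method: str = "average"
) -> tuple[pd.Series, pd.DataFrame]:
    """Partition peptides into high / heterogeneous / low phosphorylation classes.

    The peptide dendrogram (Pearson distance on log10 AUC profiles) is cut
    into ``k`` clusters; the cluster with the highest mean log10 AUC is
    labeled "high", the lowest "low", and the rest "heterogeneous". With
    k = 1 the single cluster is labeled "high".

    Returns (peptide -> label, per-cluster stats: mean log10 AUC and CV).
    """
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds number of peptides ({matrix.shape[1]})")
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("classification requires a strictly positive matrix")
    log = np.log10(matrix).sort_index(axis=1)
    z, _ = hierarchical_cluster(matrix, transform="log10", axis="features", method=method)
    assignment = fcluster(z, t=k, criterion="maxclust")
    peptides = sorted(matrix.columns)
    clusters = pd.Series(assignment, index=peptides)
    stats_rows = []
    for c in sorted(clusters.unique()):
        block = log[clusters.index[clusters == c]]
        vals = block.to_numpy()
        stats_rows.append(
            {
                "cluster": int(c),
                "n_peptides": int(block.shape[1]),
                "mean_log10_auc": float(vals.mean()),
                "cv": float(vals.std() / abs(vals.mean())) if vals.mean() != 0 else np.inf,
            }
        )
    cstats = pd.DataFrame(stats_rows).set_index("cluster")
    order = cstats["mean_log10_auc"].sort_values(ascending=False)
    label_of = {c: "heterogeneous" for c in cstats.index}
    label_of[order.index[0]] = "high"
    if len(order) > 1:
        label_of[order.index[-1]] = "low"
    labels = clusters.map(label_of).reindex(matrix.columns)
    labels.name = "label"
    cstats["label"] = [label_of[c] for c in cstats.index]
    return labels, cstats
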