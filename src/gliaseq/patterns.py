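"""PCA, hierarchical sample clustering and temporal DEG clustering.

Temporal clustering groups DEGs by their longitudinal expression shape: each
gene is reduced to an 8-vector of per-(genotype, month) medians across
replicates, distances are 1 - Pearson correlation between standardized
profiles, and an average-linkage tree is cut into k = 4 clusters. Clusters
are renumbered to the four canonical temporal patterns (1: TG down / WT
flat, 2: TG up / WT flat, 3: TG up mid-peaked / WT down, 4: TG down / WT
moderately up) by matching each cluster's median TG/WT curves against the
canonical curve templates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .simulate import DEFAULT_PATTERN_CURVES

__all__ = [
    "pca",
    "hier_cluster_samples",
    "linkage_to_newick",
    "temporal_profiles",
    "temporal_clusters",
    "gap_statistic",
]


def _standardize_genes(signals: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean unit-variance per gene; constant genes are dropped."""
    sd = signals.std(axis=1, ddof=1)
    keep = sd > 0
    sub = signals.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def pca(signals: pd.DataFrame, n_components: int | None = None):
    """PCA of samples over per-gene standardized expression.

    Returns (scores: sample x component DataFrame, variance_fractions).
    Component signs are fixed so the largest-magnitude gene loading of each
    component is positive.
    """
    if signals.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    z = _standardize_genes(signals)
    if z.empty:
        raise ValueError("constant expression matrix: PCA undefined")
    x = z.values.T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Fix signs by the largest-|loading| convention.
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    var = s**2
    frac = var / var.sum()
    k = n_components or len(s)
    scores = pd.DataFrame(
        (u * s)[:, :k], index=signals.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return scores, frac[:k]


def hier_cluster_samples(signals: pd.DataFrame):
    """Ward-linkage clustering of samples on per-gene standardized data.

    Returns (linkage matrix, leaf order as sample ids). Scipy's Ward on
    Euclidean distances is deterministic given input order, which provides
    the tie-breaking by sample order.
    """
    if signals.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    z = _standardize_genes(signals)
    x = z.values.T
    link = hierarchy.linkage(x, method="ward")
    order = hierarchy.leaves_list(link)
    return link, [signals.columns[i] for i in order]


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def temporal_profiles(signals: pd.DataFrame, meta: pd.DataFrame):
    """Per-gene median expression for every (genotype, month) cell.

    Returns (profiles, standardized, constant_genes): ``profiles`` has one
    column per cell ordered WT months then TG months; ``standardized`` is the
    zero-mean unit-variance version with constant-profile genes removed.
    """
    months = sorted(meta["month"].unique())
    cols = {}
    for g in ("WT", "TG"):
        for m in months:
            idx = meta.index[(meta["genotype"] == g) & (meta["month"] == m)]
            cols[f"{g}_{m}"] = signals[list(idx)].median(axis=1)
    profiles = pd.DataFrame(cols)
    sd = profiles.std(axis=1, ddof=1)
    constant = sorted(profiles.index[sd == 0])
    z = _standardize_genes(profiles)
    return profiles, z, constant


def _canonical_templates(months_per_genotype: int) -> np.ndarray:
    """Standardized canonical profile templates (WT curve then TG curve)."""
    templates = []
    for pat in sorted(DEFAULT_PATTERN_CURVES):
        wt = np.asarray(DEFAULT_PATTERN_CURVES[pat]["WT"], dtype=float)
        tg = np.asarray(DEFAULT_PATTERN_CURVES[pat]["TG"], dtype=float)
        if len(wt) != months_per_genotype:
            xs = np.linspace(0, 1, months_per_genotype)
            base = np.linspace(0, 1, len(wt))
            wt = np.interp(xs, base, wt)
            tg = np.interp(xs, base, tg)
        vec = np.concatenate([wt, tg])
        sd = vec.std(ddof=1)
        templates.append((vec - vec.mean()) / sd if sd > 0 else vec * 0.0)
    return np.vstack(templates)


def temporal_clusters(standardized: pd.DataFrame, k: int = 4):
    """Cluster standardized temporal profiles with 1 - r average linkage.

    Returns (assignment: gene -> cluster id Series, per-cluster median curve
    DataFrame). With k = 4 the clusters are renumbered to the canonical
    patterns by maximal correlation of the cluster median curve with the
    canonical templates (optimal one-to-one matching); otherwise clusters are
    numbered by decreasing size.
    """
    if k > len(standardized):
        raise ValueError("k exceeds the number of genes")
    dist = pdist(standardized.values, metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    raw = pd.Series(raw, index=standardized.index)

    medians = {c: standardized.loc[raw == c].median(axis=0).values for c in sorted(raw.unique())}
    labels = sorted(medians)
    if k == 4 and len(labels) == 4:
        templates = _canonical_templates(standardized.shape[1] // 2)
        cost = np.zeros((4, 4))
        for i, c in enumerate(labels):
            for j in range(4):
                cost[i, j] = -np.corrcoef(medians[c], templates[j])[0, 1]
        rows, cols = linear_sum_assignment(cost)
        mapping = {labels[i]: int(cols[list(rows).index(i)]) + 1 for i in range(4)}
    else:
        order = sorted(labels, key=lambda c: (-(raw == c).sum(), c))
        mapping = {c: i + 1 for i, c in enumerate(order)}
    assignment = raw.map(mapping)
    curves = pd.DataFrame(
        {mapping[c]: medians[c] for c in labels}, index=standardized.columns
    ).sort_index(axis=1)
    return assignment, curves


def gap_statistic(standardized: pd.DataFrame, k_max: int = 8, n_ref: int = 10, seed: int = 0):
    """Gap statistic over k = 1..k_max for the temporal clustering distance.

    Helper for choosing k; the pipeline default remains k = 4.
    """
    rng = np.random.default_rng(seed)
    x = standardized.values

    def dispersion(data, k):
        if k == 1:
            labels = np.ones(len(data), dtype=int)
        else:
            d = pdist(data, metric="correlation")
            labels = hierarchy.fcluster(hierarchy.linkage(d, "average"), t=k, criterion="maxclust")
        total = 0.0
        for c in np.unique(labels):
            sub = data[labels == c]
            if len(sub) > 1:
                total += pdist(sub, metric="correlation").sum() / len(sub)
        return total

    gaps = []
    for k in range(1, k_max + 1):
        obs = np.log(dispersion(x, k) + 1e-12)
        refs = []
        for _ in range(n_ref):
            ref = rng.uniform(x.min(axis=0), x.max(axis=0), size=x.shape)
            refs.append(np.log(dispersion(ref, k) + 1e-12))
        gaps.append(float(np.mean(refs) - obs))
    return np.array(gaps)
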