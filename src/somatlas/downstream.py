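"""Agglomerative and component analyses on gene or metagene lists.

Hierarchical clustering (Euclidean distance, configurable linkage), pairwise
sample correlation maps with intra-/inter-category histograms, FastICA
sample projections, and the three filtering benchmarks: the F-score
(inter/intra variance ratio of pairwise distances), the per-category
cluster-size fraction from a two-way clustering, and the IC-variance
fraction of a category relative to a reference union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io_formats import SampleAnnotation

LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class ClusterResult:
    axis: str
    sample_linkage: np.ndarray | None = None
    gene_linkage: np.ndarray | None = None
    sample_order: list[int] = field(default_factory=list)
    gene_order: list[int] = field(default_factory=list)


def hierarchical_cluster(
    values: np.ndarray,
    axis: str = "samples",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of a feature x sample matrix.

    axis 'samples' clusters columns, 'genes' rows, 'both' returns both
    orderings (the two-way heatmap layout).
    """
    values = np.asarray(values, dtype=float)
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage '{linkage}'")
    if axis not in ("samples", "genes", "both"):
        raise ValidationError(f"unknown axis '{axis}'")
    result = ClusterResult(axis)
    if axis in ("samples", "both"):
        if values.shape[1] < 2:
            raise ValidationError("need at least two samples to cluster")
        z = hierarchy.linkage(values.T, method=linkage, metric="euclidean")
        result.sample_linkage = z
        result.sample_order = list(hierarchy.leaves_list(z))
    if axis in ("genes", "both"):
        if values.shape[0] < 2:
            raise ValidationError("need at least two genes to cluster")
        z = hierarchy.linkage(values, method=linkage, metric="euclidean")
        result.gene_linkage = z
        result.gene_order = list(hierarchy.leaves_list(z))
    return result


def to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


@dataclass
class PairwiseCorrelationMap:
    sample_ids: list[str]
    corr: np.ndarray  # (M, M), symmetric, unit diagonal (NaN where undefined)
    intra: np.ndarray  # correlation values of same-category sample pairs
    inter: np.ndarray  # values of different-category pairs


def pcm(
    values: np.ndarray,
    sample_ids: list[str],
    annotation: SampleAnnotation | None = None,
) -> PairwiseCorrelationMap:
    """Pearson correlation over the feature dimension for all sample pairs,
    split into intra- and inter-category pairings when annotated."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if m < 2:
        raise ValidationError("need at least two samples")
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance sample(s); their correlations are NA")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.asarray(corr, dtype=float)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    labels = annotation.labels_for(sample_ids) if annotation else ["all"] * m
    intra, inter = [], []
    for i in range(m):
        for j in range(i + 1, m):
            r = corr[i, j]
            if np.isnan(r):
                continue
            (intra if labels[i] == labels[j] else inter).append(r)
    return PairwiseCorrelationMap(
        list(sample_ids), corr, np.asarray(intra), np.asarray(inter)
    )


def correlation_histograms(
    pcm_result: PairwiseCorrelationMap, bins: int = 40
) -> pd.DataFrame:
    """Binned intra/inter correlation frequency table (plot-ready)."""
    edges = np.linspace(-1.0, 1.0, bins + 1)
    intra, _ = np.histogram(pcm_result.intra, bins=edges)
    inter, _ = np.histogram(pcm_result.inter, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:],
         "intra": intra, "inter": inter}
    )


def ica_project(values: np.ndarray, n_components: int = 2, seed: int = 42) -> np.ndarray:
    """FastICA sample coordinates (samples are the observations).

    Components are ordered by decreasing coordinate variance and have their
    largest-magnitude coordinate flipped positive; the remaining sign and
    permutation indeterminacy is inherent to ICA.
    """
    from sklearn.decomposition import FastICA

    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if n_components not in (2, 3):
        raise ValidationError("n_components must be 2 or 3")
    if m <= n_components:
        raise ValidationError("need more samples than components")
    x = values.T  # samples x features
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < n_components:
        raise ValidationError("data rank below requested component count")
    ica = FastICA(
        n_components=n_components, random_state=seed,
        whiten="unit-variance", max_iter=2000, tol=1e-6,
    )
    coords = ica.fit_transform(x)
    order = np.argsort(-coords.var(axis=0), kind="stable")
    coords = coords[:, order]
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def f_score(values: np.ndarray, labels: list[str],
            categories: list[str] | None = None) -> float:
    """Inter-to-intra category dispersion of pairwise Euclidean distances
    between samples (columns of ``values``): the mean squared distance
    between samples of different categories over the mean squared distance
    within categories.  Large values mean compact, well-separated clusters;
    random labels give values near 1."""
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if categories is not None:
        keep = [i for i, lab in enumerate(labels) if lab in categories]
        values = values[:, keep]
        labels = [labels[i] for i in keep]
    m = len(labels)
    if values.shape[1] != m:
        raise ValidationError("labels must match sample columns")
    for cat in set(labels):
        if labels.count(cat) < 2:
            raise ValidationError(f"category '{cat}' has fewer than two samples")
    dists = squareform(pdist(values.T))
    intra, inter = [], []
    for i in range(m):
        for j in range(i + 1, m):
            (intra if labels[i] == labels[j] else inter).append(dists[i, j])
    if len(intra) < 1 or len(inter) < 1:
        raise ValidationError("need at least one intra and one inter pair")
    msd_intra = float(np.mean(np.square(intra)))
    msd_inter = float(np.mean(np.square(inter)))
    if msd_intra == 0:
        warnings.warn("zero intra-category dispersion; F-score is inf")
        return float("inf")
    return msd_inter / msd_intra


def ic_variance_fraction(
    coords: np.ndarray,
    labels: list[str],
    category: str,
    reference_categories: list[str],
) -> float:
    """100 * (var IC1 + var IC2 of one category) / (summed var IC1 + var IC2
    of the reference categories): the category's share of the reference
    coordinate spread (equal-variance categories split evenly)."""
    coords = np.asarray(coords, dtype=float)[:, :2]
    labels = np.asarray(labels)
    if category not in labels:
        raise ValidationError(f"category '{category}' absent")
    in_cat = labels == category
    if in_cat.sum() < 2:
        return float("nan")
    var_ref = 0.0
    for ref in reference_categories:
        in_ref = labels == ref
        if in_ref.sum() < 2:
            continue
        var_ref += coords[in_ref].var(axis=0, ddof=1).sum()
    if var_ref == 0:
        raise ValidationError("reference categories carry no variance")
    var_cat = coords[in_cat].var(axis=0, ddof=1).sum()
    return 100.0 * float(var_cat / var_ref)


def cluster_size_fraction(
    values: np.ndarray,
    gene_cluster_labels: np.ndarray,
    sample_labels: list[str],
    category: str,
) -> float:
    """Percentage of features falling in the gene clusters attributed to
    ``category``.

    Each gene cluster is attributed to the sample category in which its
    mean expression is highest (the operational reading of heatmap blocks).
    """
    values = np.asarray(values, dtype=float)
    gene_cluster_labels = np.asarray(gene_cluster_labels)
    sample_labels = np.asarray(sample_labels)
    if len(gene_cluster_labels) != values.shape[0]:
        raise ValidationError("one cluster label per feature required")
    if len(sample_labels) != values.shape[1]:
        raise ValidationError("one category label per sample required")
    categories = list(dict.fromkeys(sample_labels))
    if category not in categories:
        raise ValidationError(f"unknown category '{category}'")
    count_in_category = 0
    assigned_any = False
    for c in np.unique(gene_cluster_labels):
        members = gene_cluster_labels == c
        means = {
            cat: values[np.ix_(members, sample_labels == cat)].mean()
            for cat in categories
        }
        best = max(means, key=lambda cat: means[cat])
        if best == category:
            assigned_any = True
            count_in_category += int(members.sum())
    if not assigned_any:
        warnings.warn(f"no gene cluster attributed to '{category}'")
        return 0.0
    return 100.0 * count_in_category / len(gene_cluster_labels)
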