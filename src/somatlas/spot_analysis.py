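"""Spot segmentation on the SOM lattice and entropy specificity scoring.

Overexpression spots are connected components of nodes above a per-map
quantile threshold (underexpression symmetrically below); spots are labeled
A, B, C... (over) or a, b, c... (under) in decreasing order of their
extremal value.  The spot x sample expression matrix averages metagene
values over spot nodes, and per-sample cluster specificity is scored with a
normalized Shannon entropy.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .som_core import Assignment, SOMGrid, TrainedSOM

_ENTROPY_EPS = 1e-12


@dataclass
class Spot:
    label: str
    polarity: str  # over | under
    nodes: np.ndarray          # member node indices (one connected component)
    gene_ids: list[str]        # union of the member nodes' genes
    seed_node: int             # extremal node
    peak_value: float

    def __post_init__(self) -> None:
        if self.polarity not in ("over", "under"):
            raise ValidationError(f"unknown polarity '{self.polarity}'")


@dataclass
class SpotSet:
    spots: list[Spot]
    grid: SOMGrid
    polarity: str
    threshold: float = float("nan")
    params: dict = field(default_factory=dict)

    @property
    def C(self) -> int:
        return len(self.spots)

    def labels(self) -> list[str]:
        return [s.label for s in self.spots]

    def node_sets(self) -> list[set[int]]:
        return [set(map(int, s.nodes)) for s in self.spots]


def _spot_label(rank: int, polarity: str) -> str:
    letters = string.ascii_uppercase if polarity == "over" else string.ascii_lowercase
    if rank < 26:
        return letters[rank]
    return letters[rank // 26 - 1] + letters[rank % 26]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValidationError("connectivity must be 4 or 8")


def _components_to_spots(
    candidate: np.ndarray,
    node_values: np.ndarray,
    grid: SOMGrid,
    polarity: str,
    min_size: int,
    connectivity: int,
    assignment: Assignment | None,
) -> list[Spot]:
    structure = _connectivity_structure(connectivity)
    labeled, n_components = ndimage.label(
        candidate.reshape(grid.y, grid.x), structure=structure
    )
    labeled = labeled.ravel()
    components = [np.flatnonzero(labeled == c + 1) for c in range(n_components)]
    components = [nodes for nodes in components if len(nodes) >= min_size]
    sign = 1.0 if polarity == "over" else -1.0

    def peak(nodes: np.ndarray) -> tuple[float, int]:
        extremal = nodes[np.argmax(sign * node_values[nodes])]
        return float(node_values[extremal]), int(extremal)

    # decreasing extremal value; ties broken by lower seed-node index
    ranked = sorted(
        components,
        key=lambda nodes: (-sign * peak(nodes)[0], peak(nodes)[1]),
    )
    spots = []
    for rank, nodes in enumerate(ranked):
        peak_value, seed = peak(nodes)
        gene_ids: list[str] = []
        if assignment is not None:
            for k in nodes:
                gene_ids.extend(assignment.member_gene_ids(int(k)))
        spots.append(
            Spot(_spot_label(rank, polarity), polarity, nodes, gene_ids,
                 seed, peak_value)
        )
    return spots


def detect_spots(
    node_values: np.ndarray,
    grid: SOMGrid,
    polarity: str = "over",
    quantile_threshold: float = 0.98,
    min_size: int = 3,
    connectivity: int = 8,
    assignment: Assignment | None = None,
) -> SpotSet:
    """Segment spots by quantile thresholding + connected components.

    Overexpression: nodes with value >= the ``quantile_threshold`` quantile
    AND > 0 (on the centered scale a spot must actually be overexpressed,
    which also guards against plateaus of tied background values);
    underexpression symmetrically with the ``1 - q`` quantile, <= and < 0.
    Components smaller than ``min_size`` are suppressed.
    """
    node_values = np.asarray(node_values, dtype=float)
    if node_values.shape != (grid.K,):
        raise ValidationError("node_values must have one entry per grid node")
    if not 0.0 < quantile_threshold < 1.0:
        raise ValidationError("quantile_threshold must lie in (0, 1)")
    if polarity not in ("over", "under"):
        raise ValidationError(f"unknown polarity '{polarity}'")
    if np.ptp(node_values) == 0:
        warnings.warn("all node values equal; no spots detected")
        return SpotSet([], grid, polarity)
    if polarity == "over":
        threshold = float(np.quantile(node_values, quantile_threshold))
        candidate = (node_values >= threshold) & (node_values > 0)
    else:
        threshold = float(np.quantile(node_values, 1.0 - quantile_threshold))
        candidate = (node_values <= threshold) & (node_values < 0)
    spots = _components_to_spots(
        candidate, node_values, grid, polarity, min_size, connectivity, assignment
    )
    return SpotSet(
        spots, grid, polarity, threshold,
        {"quantile_threshold": quantile_threshold, "min_size": min_size,
         "connectivity": connectivity},
    )


def spots_from_mask(
    node_values: np.ndarray,
    mask: np.ndarray,
    grid: SOMGrid,
    polarity: str = "over",
    min_size: int = 3,
    connectivity: int = 8,
    assignment: Assignment | None = None,
) -> SpotSet:
    """Segment an explicit candidate-node mask (e.g. the in-spot nodes of a
    summary map) into labeled connected components."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.K,):
        raise ValidationError("mask must have one entry per grid node")
    spots = _components_to_spots(
        mask, np.asarray(node_values, dtype=float), grid, polarity,
        min_size, connectivity, assignment,
    )
    return SpotSet(spots, grid, polarity, float("nan"),
                   {"min_size": min_size, "connectivity": connectivity})


def global_spots(
    som: TrainedSOM,
    summary_map,
    polarity: str = "over",
    min_size: int = 3,
    connectivity: int = 8,
) -> SpotSet:
    """Global spots: connected components of the summary map's in-spot nodes,
    carrying the union of member genes from the assignment."""
    return spots_from_mask(
        summary_map.values, ~summary_map.flagged, som.grid, polarity,
        min_size, connectivity, som.assignment,
    )


def spot_expression(spot_set: SpotSet, som: TrainedSOM) -> pd.DataFrame:
    """C x M matrix of mean metagene expression per spot (rows labeled by
    spot); ``max_spot_expression`` gives the seed-metagene variant."""
    rows = [som.codebook[s.nodes].mean(axis=0) for s in spot_set.spots]
    return pd.DataFrame(rows, index=spot_set.labels(), columns=som.sample_ids)


def max_spot_expression(spot_set: SpotSet, som: TrainedSOM) -> pd.DataFrame:
    """Heatmap display variant: the profile of each spot's extremal metagene."""
    rows = [som.codebook[s.seed_node] for s in spot_set.spots]
    return pd.DataFrame(rows, index=spot_set.labels(), columns=som.sample_ids)


# ---------------------------------------------------------------------------
# entropy specificity
# ---------------------------------------------------------------------------

def cluster_specificity_entropy(expression: np.ndarray, eps: float = _ENTROPY_EPS) -> float:
    """Normalized Shannon entropy of one sample's cluster expression.

    Cluster expression values (which may be negative on the logged scale)
    are shifted to nonnegative weights ``w_c = max(e_c - min_c, 0) + eps``
    and normalized to probabilities; the entropy is divided by log2(C) so
    it ranges from 0 (one dominant cluster) to 1 (uniform expression).
    """
    e = np.asarray(expression, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValidationError("need expression of at least two clusters")
    w = np.maximum(e - e.min(), 0.0) + eps
    total = w.sum()
    if total <= 0:
        warnings.warn("all cluster weights zero; entropy set to 1 (uniform)")
        return 1.0
    p = w / total
    nz = p > 0
    h = -(p[nz] * np.log2(p[nz])).sum() / np.log2(len(e))
    return float(min(max(h, 0.0), 1.0))


def entropy_per_sample(spot_expr: pd.DataFrame) -> pd.Series:
    """Eq.-(3)-style entropy for every sample column of a spot x sample matrix."""
    if spot_expr.shape[0] < 2:
        raise ValidationError("need at least two spots/clusters")
    return pd.Series(
        {col: cluster_specificity_entropy(spot_expr[col].to_numpy())
         for col in spot_expr.columns},
        name="entropy",
    )


def compare_cluster_methods(
    expression: np.ndarray,
    sample_ids: list[str],
    cluster_assignments: dict[str, np.ndarray],
    C: int = 10,
) -> pd.DataFrame:
    """Per-sample entropy for several gene-clustering methods.

    ``cluster_assignments`` maps a method name to an (N,) integer label
    vector in [0, C); each method's cluster expression is the member mean,
    empty clusters are excluded with a warning.  Returns a long-format table
    (method, sample, entropy) ready for boxplotting.
    """
    expression = np.asarray(expression, dtype=float)
    records = []
    for method, labels in cluster_assignments.items():
        labels = np.asarray(labels)
        if len(labels) != expression.shape[0]:
            raise ValidationError(f"method '{method}': wrong label length")
        cluster_expr = []
        for c in range(C):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                warnings.warn(f"method '{method}': cluster {c} empty, excluded")
                continue
            cluster_expr.append(expression[members].mean(axis=0))
        cluster_expr = np.asarray(cluster_expr)
        if cluster_expr.shape[0] < 2:
            raise ValidationError(f"method '{method}': fewer than two clusters")
        for m, sid in enumerate(sample_ids):
            records.append(
                {"method": method, "sample": sid,
                 "entropy": cluster_specificity_entropy(cluster_expr[:, m])}
            )
    return pd.DataFrame.from_records(records)
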