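"""Per-sample metagene mosaics and the supporting maps.

Portraits color-code each lattice node with its metagene's differential
expression in one sample, in one of three contrast scales (logFC is the raw
codebook column; WAD and log-logFC are rendering-only transforms).  The
supporting maps summarize node population, profile variance, a coarse
profiling overview, and the integrated over-/underexpression spots of all
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .som_core import Assignment, SOMGrid, TrainedSOM

CONTRASTS = ("logFC", "WAD", "loglogFC")


@dataclass
class Portrait:
    sample_id: str
    values: np.ndarray  # (K,)
    contrast: str

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast '{self.contrast}'")

    def as_image(self, grid: SOMGrid) -> np.ndarray:
        return self.values.reshape(grid.y, grid.x)


@dataclass
class SupportMap:
    kind: str  # population | variance | over_summary | under_summary
    values: np.ndarray       # (K,) with NaN on flagged nodes
    flagged: np.ndarray      # (K,) bool; empty nodes (population) or
                             # out-of-spot nodes (summaries)

    def as_image(self, grid: SOMGrid) -> np.ndarray:
        return self.values.reshape(grid.y, grid.x)


@dataclass
class ProfilingMap:
    """Coarse-grained overview: aggregated profiles + member counts."""

    coarse_x: int
    coarse_y: int
    profiles: np.ndarray  # (coarse_y * coarse_x, M)
    counts: np.ndarray    # (coarse_y * coarse_x,)
    cell_of_node: np.ndarray  # (K,) coarse-cell index per fine node


def sample_portrait(som: TrainedSOM, sample_id: str, contrast: str = "logFC") -> Portrait:
    """Node values of one sample under the requested contrast scale.

    logFC is the codebook column itself.  WAD multiplies each value by its
    min-max position within the sample (emphasizing strong overexpression);
    log-logFC applies a sign-preserving log compression scaled by the
    sample's median absolute node value.
    """
    m = som.sample_ids.index(sample_id) if sample_id in som.sample_ids else None
    if m is None:
        raise ValidationError(f"sample '{sample_id}' not in this map")
    column = som.codebook[:, m].copy()
    if contrast == "logFC":
        return Portrait(sample_id, column, contrast)
    if contrast == "WAD":
        lo, hi = column.min(), column.max()
        if hi == lo:
            warnings.warn(f"flat portrait for '{sample_id}'; WAD degenerates to zeros")
            return Portrait(sample_id, np.zeros_like(column), contrast)
        weight = (column - lo) / (hi - lo)
        return Portrait(sample_id, column * weight, contrast)
    if contrast == "loglogFC":
        s = np.median(np.abs(column))
        if s == 0:
            s = 1.0
        values = np.sign(column) * np.log10(1.0 + np.abs(column) / s)
        return Portrait(sample_id, values, contrast)
    raise ValidationError(f"unknown contrast '{contrast}'")


def population_map(assignment: Assignment) -> SupportMap:
    """log10 gene count per node; empty nodes flagged (NaN), not -inf."""
    n_k = assignment.populations.astype(float)
    empty = n_k == 0
    values = np.full_like(n_k, np.nan)
    values[~empty] = np.log10(n_k[~empty])
    return SupportMap("population", values, empty)


def variance_map(som: TrainedSOM) -> SupportMap:
    """Per-node variance of the metagene profile over samples (ddof=1)."""
    if som.n_samples < 2:
        raise ValidationError("variance map needs at least two samples")
    values = som.codebook.var(axis=1, ddof=1)
    return SupportMap("variance", values, np.zeros(len(values), dtype=bool))


def profiling_map(som: TrainedSOM, coarse_x: int = 8, coarse_y: int = 8) -> ProfilingMap:
    """Population-weighted mean metagene profile per coarse cell.

    Coarse dims that do not divide the fine dims fall back to the nearest
    partition (with a warning); member counts always sum to N.
    """
    grid = som.grid
    if coarse_x > grid.x or coarse_y > grid.y:
        raise ValidationError("coarse grid may not exceed the fine grid")
    if coarse_x < 1 or coarse_y < 1:
        raise ValidationError("coarse dims must be positive")
    if grid.x % coarse_x or grid.y % coarse_y:
        warnings.warn(
            f"coarse grid {coarse_x}x{coarse_y} does not divide "
            f"{grid.x}x{grid.y}; using the nearest partition"
        )
    coords = grid.coordinates()
    cell_col = (coords[:, 0] * coarse_x / grid.x).astype(int)
    cell_row = (coords[:, 1] * coarse_y / grid.y).astype(int)
    cell = cell_row * coarse_x + cell_col
    n_cells = coarse_x * coarse_y
    profiles = np.zeros((n_cells, som.n_samples))
    counts = np.zeros(n_cells, dtype=int)
    pops = som.assignment.populations
    for c in range(n_cells):
        nodes = np.flatnonzero(cell == c)
        counts[c] = pops[nodes].sum()
        w = pops[nodes].astype(float)
        if w.sum() == 0:
            w = np.ones(len(nodes))  # unpopulated cell: plain mean
        profiles[c] = (som.codebook[nodes] * w[:, None]).sum(axis=0) / w.sum()
    return ProfilingMap(coarse_x, coarse_y, profiles, counts, cell)


def summary_maps(
    som: TrainedSOM,
    quantile: float = 0.98,
    min_size: int = 3,
    connectivity: int = 8,
) -> tuple[SupportMap, SupportMap]:
    """Integrate every sample's over-/underexpression spots into two master
    maps: per node, the max (over) or min (under) metagene value across the
    samples whose spots contain that node; 0 elsewhere."""
    from .spot_analysis import detect_spots  # local import avoids a cycle

    K = som.grid.K
    over_values = np.zeros(K)
    under_values = np.zeros(K)
    over_mask = np.zeros(K, dtype=bool)
    under_mask = np.zeros(K, dtype=bool)
    for m, sample_id in enumerate(som.sample_ids):
        column = som.codebook[:, m]
        for polarity, values, mask, pick in (
            ("over", over_values, over_mask, np.maximum),
            ("under", under_values, under_mask, np.minimum),
        ):
            spots = detect_spots(
                column, som.grid, polarity=polarity, quantile_threshold=quantile,
                min_size=min_size, connectivity=connectivity,
            )
            for spot in spots.spots:
                nodes = spot.nodes
                fresh = ~mask[nodes]
                values[nodes[fresh]] = column[nodes[fresh]]
                values[nodes[~fresh]] = pick(values[nodes[~fresh]], column[nodes[~fresh]])
                mask[nodes] = True
    return (
        SupportMap("over_summary", over_values, ~over_mask),
        SupportMap("under_summary", under_values, ~under_mask),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def expression_colormap():
    """Blue -> green -> yellow -> red -> maroon, grey for flagged nodes."""
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "somatlas",
        ["#00008b", "#2166ac", "#1a9850", "#ffff33", "#e31a1c", "#800000"],
    )
    cmap.set_bad("#999999")
    return cmap


def render_map(
    values: np.ndarray,
    grid: SOMGrid,
    path,
    title: str | None = None,
    symmetric: bool = True,
) -> None:
    """Write one node-value map as a PNG raster (one square block per node)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    image = np.asarray(values, dtype=float).reshape(grid.y, grid.x)
    masked = np.ma.masked_invalid(image)
    if symmetric:
        vmax = float(np.nanmax(np.abs(image))) if np.isfinite(image).any() else 1.0
        vmax = vmax or 1.0
        vmin = -vmax
    else:
        vmin = vmax = None
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(masked, cmap=expression_colormap(), vmin=vmin, vmax=vmax,
              origin="lower", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
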