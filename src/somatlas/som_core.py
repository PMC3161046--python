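"""Kohonen self-organizing map: training, assignment, metagene codebook.

Genes (rows of the centered expression matrix) are the training items; each
lattice node carries a metagene profile of length M.  Training is the
classic sequential algorithm: per presented item, the best-matching unit
(BMU) is the node of minimum Euclidean distance, and all nodes move toward
the item weighted by a Gaussian neighborhood of the BMU.  Learning rate and
neighborhood radius decay linearly per epoch within each phase.

The same kernel trains the second-level (sample) map, so it operates on
plain arrays; :func:`train_som` wraps it for expression matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import StateError, ValidationError
from .io_formats import ExpressionMatrix, Scale


@dataclass(frozen=True)
class SOMGrid:
    """Planar rectangular lattice; node index k = row * x + col (row-major)."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 1 or self.y < 1:
            raise ValidationError("grid dimensions must be positive")

    @property
    def K(self) -> int:
        return self.x * self.y

    def coordinates(self) -> np.ndarray:
        """(K, 2) array of (col, row) node coordinates."""
        cols, rows = np.meshgrid(np.arange(self.x), np.arange(self.y))
        return np.column_stack([cols.ravel(), rows.ravel()]).astype(float)

    def node_index(self, col: int, row: int) -> int:
        if not (0 <= col < self.x and 0 <= row < self.y):
            raise ValidationError(f"node ({col}, {row}) outside {self.x}x{self.y} grid")
        return row * self.x + col

    def node_position(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.K:
            raise ValidationError(f"node index {k} outside grid")
        return k % self.x, k // self.x


@dataclass(frozen=True)
class TrainingPhase:
    epochs: int
    radius_start: float
    radius_end: float
    alpha_start: float
    alpha_end: float

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValidationError("epochs must be non-negative")
        if min(self.radius_start, self.radius_end) <= 0:
            raise ValidationError("radii must be positive")
        if self.radius_start < self.radius_end:
            raise ValidationError("radius_start must be >= radius_end")
        if min(self.alpha_start, self.alpha_end) <= 0:
            raise ValidationError("learning rates must be positive")


def default_schedule(grid: SOMGrid) -> list[TrainingPhase]:
    """Two conventional phases: coarse ordering, then fine tuning."""
    return [
        TrainingPhase(2, max(grid.x / 2.0, 3.0), 3.0, 0.05, 0.02),
        TrainingPhase(8, 3.0, 0.7, 0.02, 0.01),
    ]


@dataclass
class Assignment:
    """Gene -> BMU mapping plus per-node bookkeeping."""

    bmu: np.ndarray          # (N,) node index per gene
    populations: np.ndarray  # (K,) gene count per node
    members: list[np.ndarray]  # per node, indices of member genes
    gene_ids: list[str]

    def member_gene_ids(self, k: int) -> list[str]:
        return [self.gene_ids[i] for i in self.members[k]]

    @property
    def n_genes(self) -> int:
        return len(self.bmu)


@dataclass
class TrainedSOM:
    grid: SOMGrid
    codebook: np.ndarray  # (K, M) metagene profiles
    assignment: Assignment
    sample_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codebook.shape[0] != self.grid.K:
            raise ValidationError("codebook rows must equal grid node count")
        if self.codebook.shape[1] != len(self.sample_ids):
            raise ValidationError("codebook columns must equal sample count")
        if len(self.assignment.populations) != self.grid.K:
            raise ValidationError("assignment populations must cover all nodes")

    @property
    def n_samples(self) -> int:
        return self.codebook.shape[1]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _pca_plane_codebook(data: np.ndarray, grid: SOMGrid, seed: int) -> np.ndarray:
    mean = data.mean(axis=0)
    centered = data - mean
    # deterministic SVD with a fixed sign convention per component
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) < 2 or s[1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn("rank < 2 covariance; falling back to random initialization")
        return _random_codebook(data, grid, seed)
    sd = s[:2] / np.sqrt(max(len(data) - 1, 1))
    pcs = vt[:2]
    for i in range(2):
        if pcs[i][np.argmax(np.abs(pcs[i]))] < 0:
            pcs[i] = -pcs[i]
    coords = grid.coordinates()
    u = 2.0 * coords[:, 0] / max(grid.x - 1, 1) - 1.0  # col -> PC1 in [-1, 1]
    v = 2.0 * coords[:, 1] / max(grid.y - 1, 1) - 1.0  # row -> PC2
    return mean + np.outer(u * sd[0], pcs[0]) + np.outer(v * sd[1], pcs[1])


def _random_codebook(data: np.ndarray, grid: SOMGrid, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    low = data.min(axis=0)
    high = data.max(axis=0)
    return rng.uniform(low, high, size=(grid.K, data.shape[1]))


def init_codebook(
    matrix: ExpressionMatrix,
    grid: SOMGrid,
    method: str = "pca_plane",
    seed: int = 0,
) -> np.ndarray:
    """Initial codebook spanning the PCA plane of the gene profiles
    (deterministic) or drawn uniformly from the per-sample value range."""
    if matrix.n_samples < 2:
        raise ValidationError("need at least two samples")
    if grid.K < 4:
        raise ValidationError("grid must have at least 4 nodes")
    if method == "pca_plane":
        return _pca_plane_codebook(matrix.values, grid, seed)
    if method == "random":
        return _random_codebook(matrix.values, grid, seed)
    raise ValidationError(f"unknown initialization method '{method}'")


# ---------------------------------------------------------------------------
# training kernel
# ---------------------------------------------------------------------------

def _best_matching_units(data: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Exact BMU per row; ties resolved to the lowest node index (argmin)."""
    # ||d - c||^2 = ||d||^2 - 2 d.c + ||c||^2 ; the ||d||^2 term is constant
    cross = data @ codebook.T
    sq = np.einsum("ij,ij->i", codebook, codebook)
    return np.argmin(sq[None, :] - 2.0 * cross, axis=1)


def _train_kernel(
    data: np.ndarray,
    grid: SOMGrid,
    codebook: np.ndarray,
    phases: list[TrainingPhase],
    seed: int,
) -> tuple[np.ndarray, list[float]]:
    """Sequential Kohonen updates; returns codebook and per-phase
    quantization errors (mean item-to-BMU distance after each phase)."""
    rng = np.random.default_rng(seed)
    coords = grid.coordinates()
    codebook = codebook.copy()
    n = len(data)
    qe: list[float] = []
    for phase in phases:
        for epoch in range(phase.epochs):
            frac = epoch / (phase.epochs - 1) if phase.epochs > 1 else 0.0
            sigma = phase.radius_start + frac * (phase.radius_end - phase.radius_start)
            alpha = phase.alpha_start + frac * (phase.alpha_end - phase.alpha_start)
            inv_two_sigma_sq = 1.0 / (2.0 * sigma * sigma)
            order = rng.permutation(n)
            for i in order:
                item = data[i]
                diff = item - codebook
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
                h = np.exp(-d2 * inv_two_sigma_sq)
                codebook += (alpha * h)[:, None] * diff
        bmus = _best_matching_units(data, codebook)
        qe.append(float(np.linalg.norm(data - codebook[bmus], axis=1).mean()))
    return codebook, qe


def assign_genes(matrix: ExpressionMatrix | np.ndarray, codebook: np.ndarray,
                 gene_ids: list[str] | None = None) -> Assignment:
    """Assign every gene to its best-matching node (minimum Euclidean
    distance; ties broken by the lowest node index)."""
    if isinstance(matrix, ExpressionMatrix):
        data = matrix.values
        gene_ids = list(matrix.gene_ids)
    else:
        data = np.asarray(matrix, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(len(data))]
    if data.shape[1] != codebook.shape[1]:
        raise ValidationError("gene profiles and codebook differ in sample count")
    # exact distances here (not the expanded form) so that crafted
    # equidistant cases resolve their ties deterministically
    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2) \
        if data.shape[0] * codebook.shape[0] <= 2_000_000 else None
    if d2 is None:
        bmu = _best_matching_units(data, codebook)
    else:
        bmu = np.argmin(d2, axis=1)
    K = codebook.shape[0]
    populations = np.bincount(bmu, minlength=K)
    members = [np.flatnonzero(bmu == k) for k in range(K)]
    return Assignment(bmu, populations, members, gene_ids)


def train_som(
    matrix: ExpressionMatrix,
    grid: SOMGrid,
    schedule: list[TrainingPhase] | TrainingPhase | None = None,
    seed: int = 42,
    init: str = "pca_plane",
) -> TrainedSOM:
    """Train the metagene map on centered gene profiles.

    ``schedule`` may be a single phase or a list of phases; the default is
    the two-phase ordering/fine-tuning schedule of :func:`default_schedule`.
    The gene presentation order is a seed-derived permutation, re-shuffled
    per epoch, so identical inputs and seeds give bit-identical results.
    """
    if matrix.scale is not Scale.CENTERED:
        raise StateError("train_som requires centered differential expression")
    if grid.K == 0:
        raise ValidationError("grid has no nodes")
    if matrix.n_genes < grid.K:
        warnings.warn(
            f"fewer genes ({matrix.n_genes}) than nodes ({grid.K}); "
            "many nodes will stay empty"
        )
    if schedule is None:
        phases = default_schedule(grid)
    elif isinstance(schedule, TrainingPhase):
        phases = [schedule]
    else:
        phases = list(schedule)
    codebook = init_codebook(matrix, grid, method=init, seed=seed)
    codebook, qe = _train_kernel(matrix.values, grid, codebook, phases, seed)
    assignment = assign_genes(matrix, codebook)
    metadata = {
        "seed": seed,
        "initialization": init,
        "schedule": [vars(p) for p in phases],
        "quantization_errors": qe,
        "n_genes": matrix.n_genes,
    }
    return TrainedSOM(grid, codebook, assignment, list(matrix.sample_ids), metadata)


def metagene_matrix(som: TrainedSOM) -> np.ndarray:
    """The K x M codebook — the compressed data set for downstream modules."""
    return som.codebook.copy()
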