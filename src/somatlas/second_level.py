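"""Second-level SOM: samples as items, metasamples as nodes; plus zoom-in.

The second-level map feeds each sample's K-dimensional metagene vector to
the same Kohonen kernel used for the gene map, on a grid with more nodes
than samples (most tiles stay empty).  Zoom-in re-runs the entire pipeline
on a sample subset, re-centering from the log scale because differential
expression depends on the sample ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import ExpressionMatrix, SampleAnnotation, Scale
from .som_core import (
    SOMGrid,
    TrainingPhase,
    _best_matching_units,
    _pca_plane_codebook,
    _train_kernel,
)


@dataclass
class SecondLevelSOM:
    grid: SOMGrid
    codebook: np.ndarray            # (K_2SOM, K) metasample profiles
    sample_ids: list[str]
    bmu: np.ndarray                 # (M,) node index per sample
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> dict[str, tuple[int, int]]:
        """sample id -> (col, row) node coordinates."""
        return {
            sid: self.grid.node_position(int(k))
            for sid, k in zip(self.sample_ids, self.bmu)
        }

    @property
    def empty_nodes(self) -> np.ndarray:
        occupied = np.zeros(self.grid.K, dtype=bool)
        occupied[self.bmu] = True
        return ~occupied


def default_second_level_grid(n_samples: int) -> SOMGrid:
    """Smallest square grid with at least twice as many nodes as samples."""
    side = math.ceil(math.sqrt(2 * n_samples))
    return SOMGrid(side, side)


def default_second_level_schedule(grid: SOMGrid) -> list[TrainingPhase]:
    return [
        TrainingPhase(20, max(grid.x / 2.0, 2.0), 2.0, 0.05, 0.02),
        TrainingPhase(30, 2.0, 1.0, 0.02, 0.01),
    ]


def train_second_level(
    metagene_matrix: np.ndarray,
    sample_ids: list[str],
    grid: SOMGrid | None = None,
    schedule: list[TrainingPhase] | None = None,
    seed: int = 42,
) -> SecondLevelSOM:
    """Map samples (columns of the K x M metagene matrix) onto a metasample
    grid; similar samples land on nearby nodes."""
    metagene_matrix = np.asarray(metagene_matrix, dtype=float)
    m = metagene_matrix.shape[1]
    if m != len(sample_ids):
        raise ValidationError("sample_ids must match metagene matrix columns")
    if m < 2:
        raise ValidationError("need at least two samples")
    if grid is None:
        grid = default_second_level_grid(m)
    if grid.K <= m:
        raise ValidationError(
            f"second-level grid must exceed the sample count (K={grid.K} <= M={m})"
        )
    if schedule is None:
        schedule = default_second_level_schedule(grid)
    data = metagene_matrix.T  # samples are the training items
    codebook = _pca_plane_codebook(data, grid, seed)
    codebook, qe = _train_kernel(data, grid, codebook, schedule, seed)
    bmu = _best_matching_units(data, codebook)
    return SecondLevelSOM(
        grid, codebook, list(sample_ids), bmu,
        {"seed": seed, "quantization_errors": qe},
    )


def zoom_in(config, sample_subset: list[str], matrix: ExpressionMatrix,
            annotation: SampleAnnotation | None = None,
            collection=None):
    """Re-run the full pipeline on a sample subset.

    The subset is re-centered from the log scale (mean-centering depends on
    the sample ensemble), then trained, segmented and annotated like the
    main run; outputs land under ``<output_dir>/zoom_<label>``.
    """
    from .cli import run_pipeline  # deferred: cli imports this module

    subset = list(dict.fromkeys(sample_subset))
    if len(subset) < 2:
        raise ValidationError("zoom-in needs at least two samples")
    missing = [s for s in subset if s not in matrix.sample_ids]
    if missing:
        raise ValidationError(f"unknown sample id(s): {', '.join(missing)}")
    if matrix.scale is Scale.CENTERED:
        raise ValidationError(
            "zoom-in requires linear or log10 input (re-centering happens "
            "within the subset)"
        )
    sub_matrix = matrix.subset_samples(subset)
    sub_config = config.replace(
        output_dir=str(config.output_path() / f"zoom_{len(subset)}samples"),
    )
    return run_pipeline(sub_config, matrix=sub_matrix, annotation=annotation,
                        collection=collection)
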