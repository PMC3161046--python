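"""Bring expression values to the centered differential-expression scale.

The working scale of the whole pipeline is the per-gene mean-centered log10
expression (differential expression in units of the logged fold change).
Optional steps: floor + log transform for linear input, a present-fraction
surrogate for detection-call filtering, and quantile normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import StateError, ValidationError
from .io_formats import ExpressionMatrix, Scale


@dataclass
class PreprocessReport:
    n_genes_in: int
    n_genes_kept: int
    normalization_applied: bool
    floor_value: float
    sample_medians_before: np.ndarray
    sample_medians_after: np.ndarray

    def __post_init__(self) -> None:
        if self.n_genes_kept > self.n_genes_in:
            raise ValidationError("kept more genes than supplied")


def _require_scale(matrix: ExpressionMatrix, scale: Scale, op: str) -> None:
    if matrix.scale is not scale:
        raise StateError(
            f"{op} requires scale '{scale.value}', got '{matrix.scale.value}'"
        )


def log_transform(matrix: ExpressionMatrix, floor: float = 1e-10) -> ExpressionMatrix:
    """log10-transform a linear-scale matrix, flooring values at ``floor``."""
    _require_scale(matrix, Scale.LINEAR, "log_transform")
    if floor <= 0:
        raise ValidationError("floor must be positive")
    return matrix.with_values(np.log10(np.maximum(matrix.values, floor)), Scale.LOG10)


def center_profiles(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean over samples (differential expression)."""
    _require_scale(matrix, Scale.LOG10, "center_profiles")
    if matrix.n_samples < 2:
        raise ValidationError("mean-centering needs at least two samples")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    # re-center once more to absorb rounding in the subtraction itself
    centered -= centered.mean(axis=1, keepdims=True)
    return matrix.with_values(centered, Scale.CENTERED)


def filter_low_expression(
    matrix: ExpressionMatrix,
    present_fraction_threshold: float = 0.0,
    level_threshold: float = -np.inf,
) -> np.ndarray:
    """Boolean mask of genes exceeding ``level_threshold`` in at least
    ``present_fraction_threshold`` of the samples (a detection-call surrogate).
    """
    _require_scale(matrix, Scale.LOG10, "filter_low_expression")
    if not 0.0 <= present_fraction_threshold <= 1.0:
        raise ValidationError("present_fraction_threshold must lie in [0, 1]")
    if present_fraction_threshold == 0.0:
        return np.ones(matrix.n_genes, dtype=bool)
    present = (matrix.values > level_threshold).mean(axis=1)
    return present >= present_fraction_threshold


def normalize_quantiles(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns to the mean-of-sorted-columns
    reference distribution; within-column rank order is preserved."""
    _require_scale(matrix, Scale.LOG10, "normalize_quantiles")
    values = matrix.values
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    normalized = np.empty_like(values)
    rows = np.arange(values.shape[0])
    for j in range(values.shape[1]):
        normalized[order[:, j], j] = reference[rows]
    return matrix.with_values(normalized, Scale.LOG10)


def prepare(
    matrix: ExpressionMatrix,
    floor: float = 1e-10,
    present_fraction_threshold: float = 0.0,
    level_threshold: float = -np.inf,
    quantile_normalize: bool = False,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Run the full preprocessing chain down to the centered scale.

    Accepts linear, log10 or already-centered input; centered input is
    passed through untouched (with a warning if other options were set).
    """
    n_in = matrix.n_genes
    medians_before = np.median(matrix.values, axis=0)
    if matrix.scale is Scale.CENTERED:
        if quantile_normalize or present_fraction_threshold > 0:
            warnings.warn("input already centered; preprocessing options ignored")
        report = PreprocessReport(
            n_in, n_in, False, floor, medians_before, medians_before
        )
        return matrix, report
    if matrix.scale is Scale.LINEAR:
        matrix = log_transform(matrix, floor=floor)
    mask = filter_low_expression(
        matrix, present_fraction_threshold, level_threshold
    )
    if not mask.all():
        matrix = matrix.subset_genes(mask)
    if quantile_normalize:
        matrix = normalize_quantiles(matrix)
    centered = center_profiles(matrix)
    report = PreprocessReport(
        n_in,
        centered.n_genes,
        quantile_normalize,
        floor,
        medians_before,
        np.median(matrix.values, axis=0),
    )
    return centered, report
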