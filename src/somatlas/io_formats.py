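"""Readers and writers for the file formats the pipeline touches.

Expression matrices are plain TSV (one header row, first column gene ids);
GCT 1.2 is accepted by skipping its two preamble lines and the Description
column.  Gene sets use the GMT interchange format; sample annotations are
two-column TSV.  Identifier matching between formats is exact string match
after whitespace trimming — mapping between id spaces is upstream curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: accepted category tags for gene sets
GENE_SET_CATEGORIES = (
    "biological_process",
    "molecular_function",
    "cellular_component",
    "custom",
)

_CATEGORY_ALIASES = {
    "biological_process": "biological_process",
    "bp": "biological_process",
    "go_bp": "biological_process",
    "molecular_function": "molecular_function",
    "mf": "molecular_function",
    "go_mf": "molecular_function",
    "cellular_component": "cellular_component",
    "cc": "cellular_component",
    "go_cc": "cellular_component",
}

_CENTERED_TOL_PER_SAMPLE = 1e-9


class Scale(str, Enum):
    """Declared scale of an expression matrix."""

    LINEAR = "linear"
    LOG10 = "log10"
    CENTERED = "centered"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with an explicit scale state.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (length N).
    sample_ids
        Unique column identifiers (length M >= 2).
    values
        N x M array of finite expression values.
    scale
        One of :class:`Scale`; ``CENTERED`` additionally requires every row
        to sum to zero within ``1e-9 * M``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.scale = Scale(self.scale)
        n, m = self.values.shape
        if n != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {n} value rows"
            )
        if m != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {m} value columns"
            )
        if n < 1:
            raise ValidationError("matrix must contain at least one gene")
        if m < 2:
            raise ValidationError("matrix must contain at least two samples")
        if len(set(self.gene_ids)) != n:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != m:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if self.scale is Scale.CENTERED:
            sums = self.values.sum(axis=1)
            tol = _CENTERED_TOL_PER_SAMPLE * m
            if np.any(np.abs(sums) > tol):
                worst = int(np.argmax(np.abs(sums)))
                raise ValidationError(
                    "centered matrix has non-zero row sum "
                    f"{sums[worst]:.3g} for gene '{self.gene_ids[worst]}'"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id '{sample_id}'") from None

    def with_values(self, values: np.ndarray, scale: Scale) -> "ExpressionMatrix":
        """Return a copy carrying new values/scale but the same ids."""
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), values, scale
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            self.scale,
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            [g for g, keep in zip(self.gene_ids, mask) if keep],
            list(self.sample_ids),
            self.values[mask],
            self.scale,
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in GENE_SET_CATEGORIES:
            raise ValidationError(f"unknown gene-set category '{self.category}'")
        if not self.members:
            raise ValidationError(f"gene set '{self.name}' has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe_hint: int | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene-set names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sets:
            counts[s.category] = counts.get(s.category, 0) + 1
        return counts


_DEFAULT_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)

UNASSIGNED = "unassigned"


@dataclass
class SampleAnnotation:
    """Mapping sample id -> category with an ordered, colored category list."""

    mapping: dict[str, str] = field(default_factory=dict)
    categories: list[str] = field(default_factory=list)
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in self.mapping.values():
            if not cat:
                raise ValidationError("empty category label")
            if cat not in self.categories:
                self.categories.append(cat)
        for i, cat in enumerate(self.categories):
            self.colors.setdefault(cat, _DEFAULT_PALETTE[i % len(_DEFAULT_PALETTE)])
        self.colors.setdefault(UNASSIGNED, "#bbbbbb")

    def category_of(self, sample_id: str) -> str:
        return self.mapping.get(sample_id, UNASSIGNED)

    def labels_for(self, sample_ids: Iterable[str]) -> list[str]:
        return [self.category_of(s) for s in sample_ids]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _validate_field_counts(path: Path, skip: int = 0) -> None:
    """Reject rows whose field count differs from the header's (pandas
    would otherwise silently truncate or pad them)."""
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline()
        expected = len(header.rstrip("\r\n").split("\t"))
        for lineno, line in enumerate(fh, start=skip + 2):
            if not line.strip():
                continue
            got = len(line.rstrip("\r\n").split("\t"))
            if got != expected:
                raise ParseError(
                    f"{path.name} line {lineno}: expected {expected} "
                    f"tab-separated fields, got {got}"
                )


def read_expression_matrix(path, scale_declared: Scale | str) -> ExpressionMatrix:
    """Read a TSV (or GCT 1.2) expression matrix.

    The first column holds gene ids, the header row sample ids.  Duplicate
    ids, missing cells and non-numeric cells are rejected with errors naming
    the offending location.
    """
    path = Path(path)
    scale = Scale(scale_declared)
    with open(path) as fh:
        first_line = fh.readline()
    if not first_line.strip():
        raise FormatError(f"{path.name}: empty file or blank header")
    is_gct = first_line.startswith("#1.2")
    _validate_field_counts(path, skip=2 if is_gct else 0)
    read_kwargs = dict(
        sep="\t", header=0, dtype=str, keep_default_na=False, na_values=[""],
        index_col=False,  # prevent silent index inference on ragged rows
    )
    try:
        if is_gct:
            df = pd.read_csv(path, skiprows=2, **read_kwargs)
            if df.shape[1] >= 2:
                df = df.drop(columns=df.columns[1])  # GCT Description column
        else:
            df = pd.read_csv(path, **read_kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from None
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: no data") from None

    if df.shape[1] < 3:
        raise FormatError(
            f"{path.name}: header must name a gene-id column and >= 2 samples"
        )
    gene_ids = [str(g).strip() for g in df.iloc[:, 0]]
    sample_ids = [str(c).strip() for c in df.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path.name}: duplicate sample ids in header")
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
        raise ValidationError(f"{path.name}: duplicate gene id '{dup}'")

    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        cell = raw.iat[i, j]
        what = "missing value" if pd.isna(cell) else f"non-numeric value '{cell}'"
        raise ParseError(
            f"{path.name}: {what} for gene '{gene_ids[i]}' "
            f"in sample column '{sample_ids[j]}'"
        )
    return ExpressionMatrix(gene_ids, sample_ids, numeric.to_numpy(dtype=float), scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as plain TSV with full float precision (round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def _category_from_description(description: str) -> str:
    return _CATEGORY_ALIASES.get(description.strip().lower(), "custom")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member1 TAB member2 ...``.

    The description field is interpreted as a category tag when it matches a
    known GO-branch alias (bp/mf/cc), else the set is tagged ``custom``.
    Duplicate members within one line are deduplicated (set semantics); lines
    with an empty member list are dropped with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name} line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0].strip()
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            if not members:
                logger.warning(
                    "%s line %d: gene set '%s' has no members, dropped",
                    path.name, lineno, name,
                )
                continue
            sets.append(GeneSet(name, _category_from_description(fields[1]), members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write(s.name + "\t" + s.category + "\t" + "\t".join(sorted(s.members)) + "\n")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_sample_annotation(path, sample_ids: Sequence[str] | None = None) -> SampleAnnotation:
    """Read a two-column TSV ``sample_id TAB category``.

    If ``sample_ids`` is given, file entries referencing unknown samples are
    ignored with a warning; samples absent from the file fall back to
    ``"unassigned"`` at lookup time.
    """
    path = Path(path)
    known = set(sample_ids) if sample_ids is not None else None
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 2 tab-separated fields"
                )
            sid, cat = fields[0].strip(), fields[1].strip()
            if lineno == 1 and sid.lower() == "sample_id":
                continue  # tolerate a header row
            if not cat:
                raise ValidationError(
                    f"{path.name} line {lineno}: empty category for '{sid}'"
                )
            if sid in mapping:
                raise ValidationError(
                    f"{path.name} line {lineno}: duplicate sample id '{sid}'"
                )
            if known is not None and sid not in known:
                logger.warning(
                    "%s line %d: sample '%s' not in the matrix, ignored",
                    path.name, lineno, sid,
                )
                continue
            mapping[sid] = cat
    return SampleAnnotation(mapping)


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    with open(path, "w") as fh:
        for sid, cat in annotation.mapping.items():
            fh.write(f"{sid}\t{cat}\n")
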