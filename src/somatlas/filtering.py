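"""Top-list feature selection for genes and metagenes.

Three ranking criteria: absolute fold change (the pooled max |dE| over
samples), profile variance, and a shrinkage-t local false discovery rate.
Metagene lists additionally carry the union of their member genes and the
per-node compression factors F_k = N / (n_k * K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .som_core import TrainedSOM

CRITERIA = ("fc", "variance", "fdr")
FDR_THRESHOLDS = (0.005, 0.01, 0.05)

_FDR_FLOOR = 1e-300


def rank_features(
    values: np.ndarray,
    ids: list[str],
    criterion: str = "fc",
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank rows by decreasing score; ties broken by id.

    fc: max over samples of |value|; variance: row variance (ddof=1);
    fdr: requires precomputed ``scores`` (lower is better, so the sign is
    flipped internally to keep 'descending score' semantics).
    """
    values = np.asarray(values, dtype=float)
    if criterion not in CRITERIA:
        raise ValidationError(f"unknown criterion '{criterion}'")
    if len(ids) != values.shape[0]:
        raise ValidationError("ids and value rows differ in length")
    if criterion == "fc":
        score = np.abs(values).max(axis=1)
    elif criterion == "variance":
        score = values.var(axis=1, ddof=1)
    else:
        if scores is None:
            raise ValidationError("criterion 'fdr' needs precomputed fdr scores")
        score = -np.asarray(scores, dtype=float)
    table = pd.DataFrame({"id": ids, "score": score})
    table = table.sort_values(
        ["score", "id"], ascending=[False, True], kind="stable", ignore_index=True
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if criterion == "fdr":
        table["score"] = -table["score"]  # back to fdr scale
    return table


@dataclass
class FilteredSet:
    criterion: str
    level: str                     # single_gene | metagene
    ids: list[str]                 # rank order
    scores: np.ndarray
    n_requested: int
    gene_union: list[str] = field(default_factory=list)  # metagene level only
    compression_factors: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)


def top_list(
    ranked: pd.DataFrame,
    n: int,
    criterion: str,
    level: str = "single_gene",
    som: TrainedSOM | None = None,
) -> FilteredSet:
    """First n features of a ranking.  For metagene-level lists (ids must be
    node indices as strings) the implied single-gene union and compression
    factors are attached from the trained map."""
    if n < 1:
        raise ValidationError("n must be positive")
    if level not in ("single_gene", "metagene"):
        raise ValidationError(f"unknown level '{level}'")
    if n > len(ranked):
        warnings.warn(f"requested {n} features but only {len(ranked)} available")
        n = len(ranked)
    head = ranked.head(n)
    ids = [str(i) for i in head["id"]]
    scores = head["score"].to_numpy()
    gene_union: list[str] = []
    factors: dict[str, float] = {}
    if level == "metagene":
        if som is None:
            raise ValidationError("metagene-level lists need the trained SOM")
        N = som.assignment.n_genes
        K = som.grid.K
        seen: set[str] = set()
        for node_id in ids:
            k = int(node_id)
            for g in som.assignment.member_gene_ids(k):
                if g not in seen:
                    seen.add(g)
                    gene_union.append(g)
            n_k = int(som.assignment.populations[k])
            factors[node_id] = compression_factor(n_k, K, N) if n_k else float("nan")
    return FilteredSet(criterion, level, ids, scores, n, gene_union, factors)


def compression_factor(n_k: int, K: int, N: int) -> float:
    """F_k = N / (n_k * K): the re-weighting a gene experiences when its
    metagene (population n_k) stands in for it."""
    if n_k < 1:
        raise ValidationError("compression factor undefined for empty nodes")
    if K < 1 or N < 1:
        raise ValidationError("K and N must be positive")
    return N / (n_k * K)


def mean_population(N: int, K: int) -> float:
    """Average minicluster size <n_k> = N / K."""
    if K < 1:
        raise ValidationError("K must be positive")
    return N / K


def population_fraction(n_k: int, N: int) -> float:
    """Percentage of all single genes held by one node: 100 * n_k / N."""
    if N < 1:
        raise ValidationError("N must be positive")
    return 100.0 * n_k / N


# ---------------------------------------------------------------------------
# shrinkage-t local FDR
# ---------------------------------------------------------------------------

def _shrunk_sd(values: np.ndarray) -> np.ndarray:
    """Gene SDs shrunk toward the median gene variance.

    The shrinkage weight follows the variance-of-variances recipe: each
    gene's sample variance has (normal-theory) estimation variance
    2 v_g^2 / (M - 1); lambda = sum of those over the squared deviations
    from the target, clipped to [0, 1].
    """
    m = values.shape[1]
    v = values.var(axis=1, ddof=1)
    v_target = np.median(v)
    denom = np.sum((v - v_target) ** 2)
    if denom <= 0:
        lam = 1.0
    else:
        lam = min(1.0, np.sum(2.0 * v**2 / (m - 1)) / denom)
    v_star = lam * v_target + (1.0 - lam) * v
    return np.sqrt(v_star)


def _local_fdr_from_pvalues(p: np.ndarray) -> np.ndarray:
    """Two-component mixture: uniform null (pi0 from p > 0.5) over a
    monotone-decreasing density estimate of the observed p-values.

    The marginal density is the Grenander-type decreasing-density MLE
    (weighted pool-adjacent-violators on the empirical-CDF slopes), which
    resolves arbitrarily small p-values; fdr = pi0 / f(p), clipped to [0, 1]
    and forced monotone non-decreasing in p.
    """
    from sklearn.isotonic import IsotonicRegression

    p = np.clip(p, 0.0, 1.0)
    n = len(p)
    pi0 = min(1.0, np.mean(p > 0.5) * 2.0)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    gaps = np.maximum(np.diff(np.concatenate([[0.0], ps])), 1e-300)
    raw_density = (1.0 / n) / gaps
    iso = IsotonicRegression(increasing=False)
    density = iso.fit_transform(
        np.arange(n, dtype=float), raw_density, sample_weight=gaps
    )
    with np.errstate(divide="ignore", over="ignore"):
        fdr_sorted = np.where(density > 0, pi0 / density, 1.0)
    fdr_sorted = np.maximum.accumulate(np.clip(fdr_sorted, 0.0, 1.0))
    fdr = np.empty(n)
    fdr[order] = fdr_sorted
    return fdr


def shrinkage_t_fdr(values: np.ndarray, ids: list[str] | None = None) -> pd.DataFrame:
    """Per-gene shrinkage-t score, p-value and local FDR.

    Per gene and sample t = dE / (s* + s0), with s* the shrunk profile SD
    and s0 a small fudge (1% of the median s*).  The gene score is the max
    |t| over samples; its p-value uses the null distribution of the maximum
    of M two-sided t variates with M - 1 df (Sidak form), which keeps null
    p-values near-uniform.  Local FDR comes from a two-component mixture
    fit (see :func:`_local_fdr_from_pvalues`).
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if m < 3:
        raise ValidationError("shrinkage-t needs at least three samples")
    if ids is None:
        ids = [f"g{i}" for i in range(n)]
    s_star = _shrunk_sd(values)
    s0 = 0.01 * np.median(s_star)
    t = values / (s_star + s0)[:, None]
    score = np.abs(t).max(axis=1)
    p_single = 2.0 * stats.t.sf(score, df=m - 1)
    p_single = np.clip(p_single, 0.0, 1.0)
    # P(max of M two-sided t stats >= observed), independence approximation
    p = 1.0 - (1.0 - p_single) ** m
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = _local_fdr_from_pvalues(p)
    return pd.DataFrame({"id": ids, "score": score, "p": p, "fdr": fdr})


def metagene_fdr(member_fdrs: np.ndarray) -> float:
    """Log-average (geometric mean) of the member genes' local FDRs."""
    member_fdrs = np.asarray(member_fdrs, dtype=float)
    if member_fdrs.size == 0:
        raise ValidationError("metagene FDR undefined for empty nodes")
    return float(10.0 ** np.mean(np.log10(np.maximum(member_fdrs, _FDR_FLOOR))))


def metagene_fdr_table(som: TrainedSOM, gene_fdr: pd.DataFrame) -> pd.DataFrame:
    """Per-node geometric-mean FDR over member genes (empty nodes NaN)."""
    fdr_of = dict(zip(gene_fdr["id"], gene_fdr["fdr"]))
    rows = []
    for k in range(som.grid.K):
        genes = som.assignment.member_gene_ids(k)
        value = metagene_fdr(np.array([fdr_of[g] for g in genes])) if genes else np.nan
        rows.append({"id": str(k), "fdr": value, "n_k": len(genes)})
    return pd.DataFrame.from_records(rows)


def venn_counts(a: FilteredSet, b: FilteredSet) -> dict[str, int]:
    """Overlap bookkeeping between two filtered sets (ids, or the gene
    unions when comparing a metagene list against a single-gene list)."""
    ids_a = set(a.gene_union if a.level == "metagene" and b.level == "single_gene" else a.ids)
    ids_b = set(b.gene_union if b.level == "metagene" and a.level == "single_gene" else b.ids)
    return {
        "only_a": len(ids_a - ids_b),
        "only_b": len(ids_b - ids_a),
        "shared": len(ids_a & ids_b),
    }
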