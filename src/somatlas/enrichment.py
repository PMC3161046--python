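"""Hypergeometric gene-set overrepresentation, per node and per spot.

The p-value is the upper tail P(X >= x) of the hypergeometric distribution
for the overlap x between a gene list (a node's minicluster or a spot's
gene union) and a gene set, drawn from the universe of genes mapped on the
SOM.  Per-node maps report raw log10 p; spot-level ranked lists report raw
p with an optional Benjamini-Hochberg column as a clearly labeled extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import GeneSet, GeneSetCollection
from .som_core import TrainedSOM
from .spot_analysis import SpotSet

_LOG_P_FLOOR = 1e-300


@dataclass
class EnrichmentResult:
    target: str          # node index (as str) or spot label
    set_name: str
    x: int               # overlap
    n: int               # list size
    N_set: int
    N_univ: int
    p: float
    log10_p: float


def hypergeom_pvalue(x: int, n: int, N_set: int, N_univ: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= x).

    X counts set members in a size-n list drawn without replacement from a
    universe of N_univ genes of which N_set belong to the set.
    """
    if not (0 <= x <= n and x <= N_set and n <= N_univ and N_set <= N_univ):
        raise ValidationError(
            f"invalid hypergeometric arguments x={x}, n={n}, "
            f"N_set={N_set}, N_univ={N_univ}"
        )
    if x == 0:
        return 1.0
    p = float(stats.hypergeom.sf(x - 1, N_univ, N_set, n))
    return min(max(p, 0.0), 1.0)


def log10_pvalue(p: float) -> float:
    return float(np.log10(max(p, _LOG_P_FLOOR)))


@dataclass
class OverrepresentationMap:
    set_name: str
    log10_p: np.ndarray   # (K,) log10 p per node (NaN on flagged nodes)
    absent: np.ndarray    # nodes containing no gene from the set (white)
    empty: np.ndarray     # nodes containing no genes at all


def overrepresentation_map(
    som: TrainedSOM,
    gene_set: GeneSet,
    universe: set[str] | None = None,
) -> OverrepresentationMap:
    """log10 hypergeometric p per lattice node for one gene set.

    The universe defaults to the genes mapped on the SOM; set members
    outside the universe are ignored.  Nodes without any set member are
    flagged absent (rendered white), empty nodes are flagged separately.
    """
    assignment = som.assignment
    if universe is None:
        universe = set(assignment.gene_ids)
    members_in_universe = gene_set.members & universe
    N_univ = len(universe)
    N_set = len(members_in_universe)
    if N_set == 0:
        warnings.warn(f"gene set '{gene_set.name}' disjoint from the universe")
    K = som.grid.K
    log10_p = np.full(K, np.nan)
    absent = np.zeros(K, dtype=bool)
    empty = assignment.populations == 0
    for k in range(K):
        n_k = int(assignment.populations[k])
        if n_k == 0:
            continue
        node_genes = assignment.member_gene_ids(k)
        x = sum(1 for g in node_genes if g in members_in_universe)
        if x == 0:
            absent[k] = True
            continue
        log10_p[k] = log10_pvalue(hypergeom_pvalue(x, n_k, N_set, N_univ))
    return OverrepresentationMap(gene_set.name, log10_p, absent, empty)


def spot_enrichment(
    spot_set: SpotSet,
    som: TrainedSOM,
    collection: GeneSetCollection,
    top_n: int = 20,
    universe: set[str] | None = None,
    benjamini_hochberg: bool = False,
) -> dict[str, pd.DataFrame]:
    """Ranked overrepresentation lists (ascending p) per spot.

    Returns one table per spot label with columns (rank, set, category, x,
    n, N_set, p, log10_p); the optional ``q_bh`` column is a
    Benjamini-Hochberg adjustment, an extension over the raw-p reporting.
    """
    assignment = som.assignment
    if universe is None:
        universe = set(assignment.gene_ids)
    N_univ = len(universe)
    results: dict[str, pd.DataFrame] = {}
    for spot in spot_set.spots:
        spot_genes = set(spot.gene_ids) & universe
        n = len(spot_genes)
        if n == 0:
            warnings.warn(f"spot '{spot.label}' contains no genes")
            results[spot.label] = pd.DataFrame(
                columns=["rank", "set", "category", "x", "n", "N_set", "p", "log10_p"]
            )
            continue
        rows = []
        for gene_set in collection:
            members = gene_set.members & universe
            if not members:
                continue
            x = len(spot_genes & members)
            p = hypergeom_pvalue(x, n, len(members), N_univ)
            rows.append(
                {"set": gene_set.name, "category": gene_set.category,
                 "x": x, "n": n, "N_set": len(members),
                 "p": p, "log10_p": log10_pvalue(p)}
            )
        table = pd.DataFrame.from_records(rows).sort_values(
            ["p", "set"], kind="stable", ignore_index=True
        )
        if benjamini_hochberg:
            n_tests = len(table)
            ranks = np.arange(1, n_tests + 1)
            q = table["p"].to_numpy() * n_tests / ranks
            table["q_bh"] = np.minimum(1.0, np.minimum.accumulate(q[::-1])[::-1])
        table = table.head(top_n).copy()
        table.insert(0, "rank", np.arange(1, len(table) + 1))
        results[spot.label] = table
    return results
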