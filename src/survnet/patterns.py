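"""Binary biclustering and gene-set enrichment.

``bimax`` enumerates every inclusion-maximal all-ones submatrix of a
binary genes x samples matrix (the maximal biclusters) by a deterministic
divide-and-conquer recursion over columns with a canonicity test, so no
bicluster is produced twice. ``jaccard_superclusters`` groups biclusters
by average-linkage clustering of their pairwise Jaccard distances.
``hypergeom_enrichment`` is the generic over-representation engine used
against user-supplied GMT collections (one-sided upper tail or two-sided
by the doubling rule), with Benjamini-Hochberg or Bonferroni adjustment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection

logger = logging.getLogger("survnet")


@dataclass(frozen=True)
class Bicluster:
    rows: frozenset[int]
    cols: frozenset[int]

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.cols)


def bimax(
    matrix: np.ndarray, min_rows: int = 2, min_cols: int = 2
) -> list[Bicluster]:
    """All inclusion-maximal all-ones submatrices meeting the size minima.

    Output is sorted by area (|rows| * |cols|) descending, then by row and
    column index sets for determinism.
    """
    m = np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("bimax input must be binary")
    m = m.astype(bool)
    n_rows, n_cols = m.shape
    if n_rows == 0 or n_cols == 0 or not m.any():
        return []

    results: list[Bicluster] = []

    def col_closure(rows: np.ndarray) -> np.ndarray:
        return m[rows].all(axis=0)

    def record(rows: np.ndarray, cols: np.ndarray) -> None:
        if rows.sum() >= min_rows and cols.sum() >= min_cols:
            results.append(
                Bicluster(
                    frozenset(np.flatnonzero(rows).tolist()),
                    frozenset(np.flatnonzero(cols).tolist()),
                )
            )

    def expand(cols: np.ndarray, rows: np.ndarray, start: int) -> None:
        record(rows, cols)
        for j in range(start, n_cols):
            if cols[j]:
                continue
            new_rows = rows & m[:, j]
            if new_rows.sum() < max(min_rows, 1):
                continue
            new_cols = col_closure(new_rows)
            # canonicity: adding column j must not pull in an earlier column
            if (new_cols[:j] & ~cols[:j]).any():
                continue
            expand(new_cols, new_rows, j + 1)

    all_rows = np.ones(n_rows, dtype=bool)
    top_cols = col_closure(all_rows)
    expand(top_cols, all_rows, 0)

    results.sort(
        key=lambda b: (-b.area, sorted(b.rows), sorted(b.cols))
    )
    return results


def verify_bicluster(matrix: np.ndarray, bc: Bicluster) -> bool:
    """True iff the bicluster is all-ones and inclusion-maximal."""
    m = np.asarray(matrix).astype(bool)
    rows = sorted(bc.rows)
    cols = sorted(bc.cols)
    if not m[np.ix_(rows, cols)].all():
        return False
    row_mask = np.zeros(m.shape[0], dtype=bool)
    row_mask[rows] = True
    col_mask = np.zeros(m.shape[1], dtype=bool)
    col_mask[cols] = True
    # no extra row supports all cols; no extra column supported by all rows
    extra_rows = m[:, col_mask].all(axis=1) & ~row_mask
    extra_cols = m[row_mask, :].all(axis=0) & ~col_mask
    return not extra_rows.any() and not extra_cols.any()


def jaccard_superclusters(
    clusters: Sequence[frozenset] | Sequence[set],
    cut: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hierarchical grouping of gene sets by Jaccard similarity.

    Returns ``(jaccard_matrix, linkage_matrix, labels)`` where clusters
    whose average Jaccard distance is below ``1 - cut``... the tree is cut
    at distance ``1 - cut`` (so ``cut`` is a similarity threshold).
    """
    sets = [frozenset(c) for c in clusters]
    if len(sets) < 2:
        raise ValueError("need at least 2 clusters")
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty cluster in input")
    k = len(sets)
    jac = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            jac[i, j] = jac[j, i] = inter / union
    z = linkage(squareform(1.0 - jac, checks=False), method="average")
    labels = fcluster(z, t=1.0 - cut, criterion="distance")
    return jac, z, labels


def hypergeom_enrichment(
    query: set[str] | Sequence[str],
    collection: GeneSetCollection,
    universe: set[str] | Sequence[str],
    sided: str = "one",
    adjust: str = "BH",
) -> pd.DataFrame:
    """Over-representation of the query in each gene set of the collection.

    One-sided upper-tail p = P(X >= x) for X ~ Hypergeom(N, K, n) with N
    the universe size, K the set size (intersected with the universe), n
    the query size, x the overlap. Two-sided doubles the smaller tail.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info(
            "hypergeom_enrichment: %d query gene(s) outside the universe were dropped",
            len(outside),
        )
        query &= universe
    n_uni = len(universe)
    n_query = len(query)
    rows = []
    for name, gs in collection:
        members = gs.members & universe
        k = len(members)
        x = len(query & members)
        if sided == "one":
            p = float(hypergeom.sf(x - 1, n_uni, k, n_query))
        elif sided == "two":
            upper = float(hypergeom.sf(x - 1, n_uni, k, n_query))
            lower = float(hypergeom.cdf(x, n_uni, k, n_query))
            p = min(1.0, 2.0 * min(upper, lower))
        else:
            raise ValueError(f"unknown sided {sided!r}")
        rows.append((name, x, k, n_query, n_uni, p))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"]
    ).set_index("set")
    if len(df):
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        df["p_adj"] = multipletests(df["p"].to_numpy(), method=method)[1]
    else:
        df["p_adj"] = []
    return df.sort_values(["p", "set"], kind="stable")
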