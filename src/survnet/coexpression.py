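"""Weighted co-expression network core: soft-threshold selection, adjacency
and topological overlap (TOM), module detection by average-linkage
clustering of dissTOM, module eigengenes, eigengene-based module merging,
and module-trait association.

The adjacency is a_ij = |cor(x_i, x_j)|^beta (unsigned, default) or
((1 + cor)/2)^beta (signed). The soft power beta is the smallest candidate
whose scale-free topology fit R^2 reaches the target (default 0.85).
Module detection uses a static cut of the average-linkage dendrogram at a
quantile of the merge heights — a deliberate simplification of dynamic
tree cutting; recovery of planted modules, not label-for-label equality
with any particular implementation, is the contract. Modules whose
eigengenes correlate above 1 - merge_cut_height (default 0.25) are merged
iteratively until stable, which makes merging idempotent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import ClinicalTable, ExpressionMatrix

logger = logging.getLogger("survnet")


# ---------------------------------------------------------------------------
# soft threshold


@dataclass
class SoftThresholdResult:
    powers: list[int]
    r2: np.ndarray  # signed scale-free fit per power
    mean_connectivity: np.ndarray
    chosen: int
    reached_target: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "signed_r2": self.r2,
                "mean_connectivity": self.mean_connectivity,
                "chosen": [p == self.chosen for p in self.powers],
            }
        )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are split into 10 equal-occupancy bins; because such
    bins hold the same count by construction, the regression uses the
    empirical density (count / (total * bin width)) of each bin against
    its mean connectivity, both log10. The R^2 is negated when the slope
    is positive (scale-free topology requires a decreasing density).
    """
    k = k[k > 0]
    if k.size < 2 * n_bins:
        return 0.0
    order = np.sort(k)
    chunks = np.array_split(order, n_bins)
    edges = [order[0]] + [
        0.5 * (chunks[i][-1] + chunks[i + 1][0]) for i in range(len(chunks) - 1)
    ] + [order[-1]]
    xs, ys = [], []
    total = k.size
    for i, c in enumerate(chunks):
        width = edges[i + 1] - edges[i]
        if c.size == 0 or width <= 0:
            continue
        xs.append(np.log10(c.mean()))
        ys.append(np.log10(c.size / (total * width)))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.size < 3 or np.ptp(xs) == 0:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r**2
    return -r2 if slope > 0 else r2


def _adjacency(
    expr_values: np.ndarray, beta: float, network_type: str = "unsigned"
) -> np.ndarray:
    corr = np.corrcoef(expr_values)
    if np.isnan(corr).any():
        bad = np.unique(np.where(np.isnan(corr))[0])
        raise ValueError(f"constant genes produce undefined correlations: rows {bad[:5]}")
    if network_type == "unsigned":
        a = np.abs(corr) ** beta
    elif network_type == "signed":
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 0.0)
    return a


def filter_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero variance across samples (undefined correlations)."""
    values = np.asarray(expr.values, dtype=float)
    keep = values.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_constant_genes: removed %d constant gene(s)", dropped)
        return expr.subset_genes([g for g, k in zip(expr.gene_ids, keep) if k])
    return expr


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.85,
    network_type: str = "unsigned",
    min_samples: int = 15,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit reaches ``r2_target``."""
    values = np.asarray(expr.values, dtype=float)
    if expr.n_samples < min_samples:
        logger.warning(
            "pick_soft_threshold: only %d samples (recommended minimum %d)",
            expr.n_samples,
            min_samples,
        )
    keep = values.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("pick_soft_threshold: removed %d constant gene(s)", dropped)
    values = values[keep]
    corr = np.corrcoef(values)
    abs_corr = np.abs(corr)
    signed_base = (1.0 + corr) / 2.0
    r2s, conns = [], []
    for beta in powers:
        a = (abs_corr if network_type == "unsigned" else signed_base) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2s.append(_scale_free_fit(k))
        conns.append(k.mean())
    r2s = np.asarray(r2s)
    above = [p for p, r2 in zip(powers, r2s) if r2 >= r2_target]
    if above:
        chosen, reached = above[0], True
    else:
        chosen, reached = list(powers)[int(np.argmax(r2s))], False
        logger.warning(
            "pick_soft_threshold: no power reached R^2 >= %.2f; using argmax %d",
            r2_target,
            chosen,
        )
    return SoftThresholdResult(list(powers), r2s, np.asarray(conns), chosen, reached)


# ---------------------------------------------------------------------------
# TOM


def tom_from_expression(
    expr: ExpressionMatrix, beta: float, network_type: str = "unsigned"
) -> np.ndarray:
    """Topological overlap matrix of the soft-thresholded adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj (u != i, j) and k_i the node connectivity;
    TOM_ii = 1.
    """
    values = np.asarray(expr.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    a = _adjacency(values, beta, network_type)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of a is 0, so u = i and u = j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# modules


@dataclass
class ModuleSet:
    """Gene-to-module assignment (0 = unassigned) plus eigengenes."""

    gene_ids: list[str]
    labels: np.ndarray  # int per gene, 0 = unassigned
    eigengenes: Optional[pd.DataFrame] = None  # samples x modules ("ME1", ...)
    merge_heights: Optional[np.ndarray] = None
    merge_history: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(int(m) for m in self.labels) - {0})

    def module_sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def members(self, module: int) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.labels) if m == module]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.labels.astype(int)},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Drop clusters below the size minimum and rank the rest by size."""
    out = np.zeros_like(labels)
    sizes = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = labels == lab
        if members.sum() >= min_module_size:
            sizes.append((int(members.sum()), int(lab)))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, old) in enumerate(sizes, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    diss_tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height_quantile: float = 0.90,
) -> ModuleSet:
    """Average-linkage clustering of dissTOM with a static quantile cut.

    Clusters smaller than ``min_module_size`` are labeled 0; modules are
    numbered 1.. by decreasing size.
    """
    d = np.asarray(diss_tom, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissTOM must be square and symmetric")
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    raw = fcluster(z, t=cut, criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    if labels.max() <= 1 and (labels > 0).all():
        logger.warning("detect_modules: all genes fell into a single module")
    return ModuleSet(list(gene_ids), labels, merge_heights=heights)


def module_eigengenes(
    expr: ExpressionMatrix, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's standardized expression.

    Eigengenes are standardized (mean 0, SD 1 across samples) and
    sign-oriented so that they correlate non-negatively with the module's
    average standardized expression. Returns (samples x modules frame,
    explained-variance fraction per module).
    """
    values = np.asarray(expr.values, dtype=float)
    labels = np.asarray(labels)
    mes = {}
    explained = {}
    for mod in sorted(set(int(m) for m in labels) - {0}):
        sub = values[labels == mod, :]
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        zs = (sub - sub.mean(axis=1, keepdims=True)) / sd
        if zs.shape[0] == 1:
            me = zs[0]
            explained[mod] = 1.0
            logger.info("module_eigengenes: module %d has a single gene", mod)
        else:
            u, s, vt = np.linalg.svd(zs.T, full_matrices=False)
            me = u[:, 0]
            explained[mod] = float(s[0] ** 2 / np.sum(s**2))
        me = (me - me.mean()) / me.std(ddof=1)
        avg = zs.mean(axis=0)
        if np.corrcoef(me, avg)[0, 1] < 0:
            me = -me
        mes[f"ME{mod}"] = me
    frame = pd.DataFrame(mes, index=pd.Index(expr.sample_ids, name="sample_id"))
    return frame, explained


def merge_modules(
    expr: ExpressionMatrix, module_set: ModuleSet, merge_cut_height: float = 0.25
) -> ModuleSet:
    """Merge modules whose eigengene dissimilarity 1 - cor falls below the cut.

    Average-linkage clustering of eigengenes, merge, recompute eigengenes,
    and iterate until no pair merges — so applying the operation twice
    changes nothing.
    """
    labels = module_set.labels.copy()
    history: list[tuple[int, ...]] = []
    while True:
        mods = sorted(set(int(m) for m in labels) - {0})
        if len(mods) < 2:
            break
        mes, _ = module_eigengenes(expr, labels)
        me_mat = mes[[f"ME{m}" for m in mods]].to_numpy().T
        diss = 1.0 - np.corrcoef(me_mat)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        new_labels = np.zeros_like(labels)
        for new_id, grp in enumerate(sorted(set(groups)), start=1):
            merged = [mods[i] for i in range(len(mods)) if groups[i] == grp]
            if len(merged) > 1:
                history.append(tuple(merged))
            for old in merged:
                new_labels[labels == old] = new_id
        labels = new_labels
    labels = _relabel_by_size(labels, 1)
    mes, _ = module_eigengenes(expr, labels)
    return ModuleSet(
        module_set.gene_ids,
        labels,
        eigengenes=mes,
        merge_heights=module_set.merge_heights,
        merge_history=module_set.merge_history + history,
    )


# ---------------------------------------------------------------------------
# module-trait association


def _correlation_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation with n-2 df."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _trait_vector(clinical: ClinicalTable, trait: str) -> tuple[np.ndarray, str]:
    kind = clinical.trait_types[trait]
    col = clinical.traits[trait]
    if kind == "continuous":
        return col.to_numpy(dtype=float), "pearson"
    codes = pd.Categorical(col).codes.astype(float)
    codes[codes < 0] = np.nan
    return codes, "spearman"


def module_trait_association(
    eigengenes: pd.DataFrame, clinical: ClinicalTable
) -> pd.DataFrame:
    """Correlate each module eigengene with each clinical trait.

    Pearson for continuous traits, Spearman for categorical/ordinal; p from
    the t approximation on complete cases; Bonferroni over all
    module x trait pairs.
    """
    rows = []
    traits = list(clinical.traits.columns)
    n_pairs = len(eigengenes.columns) * len(traits)
    for me_name in eigengenes.columns:
        me = eigengenes[me_name].to_numpy(dtype=float)
        for trait in traits:
            tv, method = _trait_vector(clinical, trait)
            ok = ~np.isnan(tv)
            n = int(ok.sum())
            if n < 4:
                rows.append((me_name, trait, method, np.nan, n, np.nan, np.nan, False))
                continue
            if method == "pearson":
                r = float(np.corrcoef(me[ok], tv[ok])[0, 1])
            else:
                r = float(stats.spearmanr(me[ok], tv[ok]).statistic)
            p = _correlation_p(r, n)
            p_adj = min(1.0, p * n_pairs) if np.isfinite(p) else np.nan
            rows.append(
                (me_name, trait, method, r, n, p, p_adj, bool(p_adj < 0.05))
            )
    return pd.DataFrame(
        rows,
        columns=["module", "trait", "method", "r", "n", "p", "p_bonferroni", "significant"],
    )


def module_significance(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    clinical: ClinicalTable,
    trait: str,
) -> pd.Series:
    """Mean absolute gene-trait correlation per module."""
    tv, method = _trait_vector(clinical, trait)
    order = {s: i for i, s in enumerate(clinical.sample_ids)}
    col = np.array([order[s] for s in expr.sample_ids])
    tv = tv[col]
    ok = ~np.isnan(tv)
    values = np.asarray(expr.values, dtype=float)[:, ok]
    tvo = tv[ok]
    out = {}
    for mod in sorted(set(int(m) for m in labels) - {0}):
        sub = values[np.asarray(labels) == mod]
        gs = []
        for row in sub:
            if row.std() == 0 or tvo.std() == 0 or ok.sum() < 3:
                gs.append(np.nan)
            elif method == "pearson":
                gs.append(abs(np.corrcoef(row, tvo)[0, 1]))
            else:
                gs.append(abs(stats.spearmanr(row, tvo).statistic))
        out[mod] = float(np.nanmean(gs)) if len(gs) else np.nan
    s = pd.Series(out, name="module_significance")
    s.index.name = "module"
    return s
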