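"""Group-level analyses: normalization, differential expression between the
long-term (LT) and short-term (ST) survival groups, Kaplan-Meier / log-rank
prognostic screening, and centroid-correlation subtype classification.

Differential expression is a self-contained negative-binomial Wald test:
median-of-ratios size factors, group means on the normalized scale,
method-of-moments dispersion, and a Wald statistic on the log2 fold change
referred to a t distribution with n-2 degrees of freedom (appropriate for
the very small group sizes this pipeline targets). There is no dispersion
or fold-change shrinkage. Genes are classified up/down at
|log2FC| >= 2 with unadjusted p < 0.05 by default.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    GROUP_LT,
    GROUP_ST,
    SCALE_LOGNORM,
    ClinicalTable,
    ExpressionMatrix,
    RunConfig,
)

logger = logging.getLogger("survnet")

_LN2 = math.log(2.0)


class NormalizationError(ValueError):
    pass


def size_factors(counts: ExpressionMatrix, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each gene positive in all samples, the ratio of its count to its
    geometric mean across samples is formed; a sample's factor is the
    median of those ratios. With ``pseudo_reference`` genes with any zero
    are still used via a positive-count geometric mean (fallback for very
    sparse matrices).
    """
    x = np.asarray(counts.values, dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        if not pseudo_reference:
            raise NormalizationError(
                "no gene has positive counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        any_pos = (x > 0).any(axis=1)
        sub = x[any_pos]
        with np.errstate(divide="ignore"):
            logx = np.where(sub > 0, np.log(sub), np.nan)
        geo = np.exp(np.nanmean(logx, axis=1))
        ratios = sub / geo[:, None]
        sf = np.nanmedian(np.where(sub > 0, ratios, np.nan), axis=0)
    else:
        sub = x[all_pos]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        sf = np.median(sub / geo[:, None], axis=0)
    if (sf <= 0).any():
        raise NormalizationError("non-positive size factor computed")
    return sf


def normalize_log(
    counts: ExpressionMatrix, sf: np.ndarray, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount)."""
    sf = np.asarray(sf, dtype=float)
    if (sf <= 0).any():
        raise NormalizationError("size factors must be positive")
    vals = np.log2(np.asarray(counts.values, dtype=float) / sf[None, :] + pseudocount)
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, vals, SCALE_LOGNORM)


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DegTable:
    """Per-gene differential-expression results (LT vs ST)."""

    table: pd.DataFrame  # index gene_id; baseMean, log2FC, se, stat, p, direction
    log2fc_up: float
    log2fc_down: float
    p_threshold: float

    def genes_with_direction(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["direction"] == direction])

    @property
    def deg_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] != "ns"])


def classify_direction(
    log2fc: np.ndarray,
    p: np.ndarray,
    up: float = 2.0,
    down: float = -2.0,
    p_threshold: float = 0.05,
) -> np.ndarray:
    """Pure threshold rule: up iff log2FC >= up and p < p_threshold; down symmetric."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.full(log2fc.shape, "ns", dtype=object)
    sig = p < p_threshold
    out[(log2fc >= up) & sig] = "up"
    out[(log2fc <= down) & sig] = "down"
    return out


def differential_expression(
    counts: ExpressionMatrix,
    clinical: ClinicalTable,
    cfg: Optional[RunConfig] = None,
) -> DegTable:
    """NB Wald test of LT vs ST on median-of-ratios normalized counts."""
    cfg = cfg or RunConfig()
    groups = np.array(clinical.group)
    order = {s: i for i, s in enumerate(clinical.sample_ids)}
    col = np.array([order[s] for s in counts.sample_ids])
    groups = groups[col]
    lt = groups == GROUP_LT
    st = groups == GROUP_ST
    n_lt, n_st = int(lt.sum()), int(st.sum())
    if n_lt < 2 or n_st < 2:
        raise ValueError("each group needs at least 2 samples")

    sf = size_factors(counts)
    norm = np.asarray(counts.values, dtype=float) / sf[None, :]
    pc = cfg.pseudocount

    m_lt = norm[:, lt].mean(axis=1)
    m_st = norm[:, st].mean(axis=1)
    base_mean = norm.mean(axis=1)

    v_lt = norm[:, lt].var(axis=1, ddof=1)
    v_st = norm[:, st].var(axis=1, ddof=1)
    pooled_var = ((n_lt - 1) * v_lt + (n_st - 1) * v_st) / (n_lt + n_st - 2)
    pooled_mean = (n_lt * m_lt + n_st * m_st) / (n_lt + n_st)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / np.square(pooled_mean)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, 1e-8)

    log2fc = np.log2((m_lt + pc) / (m_st + pc))

    def var_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        var_mean = (m + alpha * np.square(m)) / n
        return var_mean / (np.square(m + pc) * _LN2**2)

    se = np.sqrt(var_log2_mean(m_lt, n_lt) + var_log2_mean(m_st, n_st))
    zero = base_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    df = n_lt + n_st - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df=df)
    p = np.where(zero | (se == 0), 1.0, p)
    if zero.any():
        logger.info("differential_expression: %d constant-zero gene(s) set ns", zero.sum())

    direction = classify_direction(
        log2fc, p, cfg.log2fc_up, cfg.log2fc_down, cfg.deg_p_threshold
    )
    direction[zero] = "ns"
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "direction": direction,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return DegTable(table, cfg.log2fc_up, cfg.log2fc_down, cfg.deg_p_threshold)


# ---------------------------------------------------------------------------
# survival


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimator with right censoring.

    Returns a step table with one row per distinct event time plus t=0;
    ``survival`` is S(t) just after each time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = [(0.0, 1.0, int(times.size), 0)]
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), s, at_risk, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    Standard observed-minus-expected statistic with the hypergeometric
    variance at each distinct event time, 1 degree of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        died = (times == t) & (events == 1)
        d_tot = int(died.sum())
        d1 = int((died & (group == 1)).sum())
        e1 = d_tot * n1 / n_tot
        o_minus_e += d1 - e1
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_survival(
    expression_row: np.ndarray,
    times: Sequence[float],
    events: Sequence[int],
    split: str = "median",
) -> dict:
    """Screen one gene: split samples on expression and log-rank the groups.

    ``median``: high = expression strictly above the median (ties go to the
    low group). ``tertile``: high vs low third, middle dropped.
    """
    x = np.asarray(expression_row, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if split == "median":
        cut = np.median(x)
        high = x > cut
        keep = np.ones_like(high)
        rule = f"median>{cut:g}"
    elif split == "tertile":
        lo_cut, hi_cut = np.quantile(x, [1 / 3, 2 / 3])
        high = x > hi_cut
        keep = (x <= lo_cut) | high
        rule = f"tertile[{lo_cut:g},{hi_cut:g}]"
    else:
        raise ValueError(f"unknown split {split!r}")
    n_high = int(high[keep].sum())
    n_low = int(keep.sum()) - n_high
    if n_high < 2 or n_low < 2:
        return {
            "split_rule": rule,
            "n_low": n_low,
            "n_high": n_high,
            "chi2": np.nan,
            "p": np.nan,
            "prognostic": False,
            "testable": False,
        }
    chi2, p = logrank_test(times[keep], events[keep], high[keep].astype(int))
    return {
        "split_rule": rule,
        "n_low": n_low,
        "n_high": n_high,
        "chi2": chi2,
        "p": p,
        "prognostic": bool(p < 0.05),
        "testable": True,
    }


def survival_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: Optional[Sequence[str]] = None,
    split: str = "median",
) -> pd.DataFrame:
    """Log-rank screen of each gene (all samples pooled by default)."""
    order = {s: i for i, s in enumerate(expr.sample_ids)}
    col = np.array([order[s] for s in clinical.sample_ids])
    times = clinical.os_months
    events = clinical.event
    ok = ~np.isnan(times)
    rows = {}
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for g in genes if genes is not None else expr.gene_ids:
        x = expr.values[gene_pos[g], col][ok]
        rows[g] = logrank_survival(x, times[ok], events[ok], split=split)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# centroid classification


@dataclass
class CentroidModel:
    """Reference subtype centroids (genes x subtypes, log scale)."""

    subtypes: list[str]
    gene_ids: list[str]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.subtypes) < 2:
            raise ValueError("need at least 2 subtypes")
        if self.centroids.shape != (len(self.gene_ids), len(self.subtypes)):
            raise ValueError("centroid matrix shape mismatch")


def centroid_classify(
    expr: ExpressionMatrix, model: CentroidModel, min_genes: int = 10
) -> pd.DataFrame:
    """Assign each sample the subtype whose centroid it best correlates with.

    Pearson correlation on the gene intersection; ties broken by subtype
    name order.
    """
    common = [g for g in model.gene_ids if g in set(expr.gene_ids)]
    if len(common) < min_genes:
        raise ValueError(
            f"only {len(common)} genes shared between expression and centroids "
            f"(need >= {min_genes})"
        )
    e = expr.subset_genes(common).values.astype(float)
    cpos = {g: i for i, g in enumerate(model.gene_ids)}
    c = model.centroids[[cpos[g] for g in common], :]
    scores = np.zeros((expr.n_samples, len(model.subtypes)))
    for j in range(expr.n_samples):
        for k in range(len(model.subtypes)):
            scores[j, k] = np.corrcoef(e[:, j], c[:, k])[0, 1]
    name_order = np.argsort(model.subtypes, kind="stable")
    best = []
    for j in range(expr.n_samples):
        mx = scores[j].max()
        cand = [k for k in name_order if scores[j, k] >= mx - 1e-12]
        best.append(model.subtypes[cand[0]])
    df = pd.DataFrame(scores, index=expr.sample_ids, columns=model.subtypes)
    df.insert(0, "best_subtype", best)
    df.index.name = "sample_id"
    return df
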