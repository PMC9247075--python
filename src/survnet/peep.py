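"""Individual perturbation expression profiles (PEEPs).

Each target (by default long-term survivor) sample is scored gene-by-gene
against the reference (short-term) group: z = (x - mu_ref) / sd_ref, with
the reference SD using the n-1 denominator. |z| >= 2 flags a gene as
perturbed in that individual; positive z is up-regulation. A permutation
null reshuffles the ST/LT group labels (default 500 times) and collects
the per-target-sample perturbed-gene counts to give each observed sample
an add-one empirical p-value.

Input is expected on the log2-normalized scale, where SD-unit thresholds
are well behaved. Genes with zero reference SD get z = 0 and are reported
in a QC list rather than producing infinities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    GROUP_LT,
    GROUP_ST,
    ClinicalTable,
    ConfigError,
    ExpressionMatrix,
)


@dataclass
class PerturbationProfileSet:
    gene_ids: list[str]
    target_sample_ids: list[str]
    z: np.ndarray  # genes x targets
    calls: np.ndarray  # binary, same shape
    threshold: float
    ref_mean: np.ndarray
    ref_sd: np.ndarray
    n_ref: int
    zero_sd_genes: list[str] = field(default_factory=list)

    @property
    def per_sample_counts(self) -> np.ndarray:
        return self.calls.sum(axis=0)

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.target_sample_ids,
        )

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls.astype(int), index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.target_sample_ids,
        )


@dataclass
class PermutationNullSummary:
    B: int
    null_counts: np.ndarray  # B * n_target_per_perm pooled counts
    observed_counts: np.ndarray
    empirical_p: np.ndarray
    target_sample_ids: list[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "observed_counts": {
                s: int(c) for s, c in zip(self.target_sample_ids, self.observed_counts)
            },
            "empirical_p": {
                s: float(p) for s, p in zip(self.target_sample_ids, self.empirical_p)
            },
            "null_count_mean": float(self.null_counts.mean()),
            "null_count_quantiles": {
                q: float(np.quantile(self.null_counts, float(q)))
                for q in ("0.05", "0.5", "0.95")
            },
        }


def _zscores(
    values: np.ndarray, ref_cols: np.ndarray, target_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = values[:, ref_cols]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values[:, target_cols] - mu[:, None]) / sd[:, None]
    z = np.where(sd[:, None] > 0, z, 0.0)
    return z, mu, sd


def compute_peep(
    target: ExpressionMatrix,
    reference: ExpressionMatrix,
    threshold: float = 2.0,
) -> PerturbationProfileSet:
    """Score each target sample against the reference group."""
    if target.gene_ids != reference.gene_ids:
        mism = [
            g
            for g in (set(target.gene_ids) ^ set(reference.gene_ids))
        ]
        raise ValueError(
            "gene universes differ between target and reference; first "
            f"mismatches: {sorted(mism)[:5] or 'same set, different order'}"
        )
    if reference.n_samples < 3:
        raise ValueError("reference group needs at least 3 samples")
    values = np.concatenate(
        [np.asarray(reference.values, float), np.asarray(target.values, float)], axis=1
    )
    ref_cols = np.arange(reference.n_samples)
    tgt_cols = np.arange(reference.n_samples, values.shape[1])
    z, mu, sd = _zscores(values, ref_cols, tgt_cols)
    calls = (np.abs(z) >= threshold).astype(np.int8)
    zero_sd = [g for g, s in zip(target.gene_ids, sd) if s == 0]
    return PerturbationProfileSet(
        list(target.gene_ids),
        list(target.sample_ids),
        z,
        calls,
        threshold,
        mu,
        sd,
        reference.n_samples,
        zero_sd,
    )


def peep_from_cohort(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    threshold: float = 2.0,
    target_group: str = GROUP_LT,
) -> PerturbationProfileSet:
    """PEEPs for one group against the other as reference (default LT vs ST)."""
    ref_group = GROUP_ST if target_group == GROUP_LT else GROUP_LT
    target = expr.subset_samples(clinical.samples_in_group(target_group))
    reference = expr.subset_samples(clinical.samples_in_group(ref_group))
    return compute_peep(target, reference, threshold)


def permutation_null(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    B: int = 500,
    threshold: float = 2.0,
    seed: int = 0,
    target_group: str = GROUP_LT,
) -> PermutationNullSummary:
    """Reshuffle ST/LT labels B times and collect null perturbed-gene counts.

    Group sizes are preserved exactly under each permutation. Each observed
    target sample gets the add-one empirical p
    (1 + #{null counts >= observed}) / (B * n_target + 1).
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    observed = peep_from_cohort(expr, clinical, threshold, target_group)
    obs_counts = observed.per_sample_counts

    order = {s: i for i, s in enumerate(expr.sample_ids)}
    tgt_idx = np.array([order[s] for s in clinical.samples_in_group(target_group)])
    ref_group = GROUP_ST if target_group == GROUP_LT else GROUP_LT
    ref_idx = np.array([order[s] for s in clinical.samples_in_group(ref_group)])
    n_ref, n_tgt = len(ref_idx), len(tgt_idx)
    all_idx = np.concatenate([ref_idx, tgt_idx])
    values = np.asarray(expr.values, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null_counts = np.empty((B, n_tgt), dtype=np.int64)
    for b in range(B):
        perm = rng.permutation(all_idx)
        z, _, _ = _zscores(values, perm[:n_ref], perm[n_ref:])
        null_counts[b] = (np.abs(z) >= threshold).sum(axis=0)
    pooled = null_counts.ravel()
    denom = B * n_tgt + 1
    emp_p = (1 + (pooled[None, :] >= obs_counts[:, None]).sum(axis=1)) / denom
    return PermutationNullSummary(
        B, pooled, obs_counts, emp_p, observed.target_sample_ids, seed
    )


def sharing_frequency(calls: pd.DataFrame | np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Per-gene number of target samples perturbed, plus the inverse summary.

    Returns ``(per_gene, by_count)`` where ``by_count[k]`` is the number of
    genes perturbed in exactly k samples (k >= 1).
    """
    if isinstance(calls, pd.DataFrame):
        freq = calls.sum(axis=1).astype(int)
    else:
        arr = np.asarray(calls)
        freq = pd.Series(arr.sum(axis=1).astype(int))
    by_count = freq[freq > 0].value_counts().sort_index()
    by_count.index.name = "n_samples"
    freq.name = "n_samples_perturbed"
    return freq, by_count
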