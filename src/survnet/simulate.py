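"""Synthetic two-group survival cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume for a small pancreatic-cancer style cohort: 10 short-term (ST) and
9 long-term (LT) survivors, negative-binomial counts with per-sample
library-size factors, planted group-level differentially expressed genes,
planted co-expression modules driven by latent factors (one of which is
correlated with a continuous clinical trait), planted per-LT-individual
expression perturbations (private and shared), and a scale-free
interaction network with a planted, densified disease-gene neighborhood.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, so identical seeds give
byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    GROUP_LT,
    GROUP_ST,
    ClinicalTable,
    ConfigError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
)

_LN2 = math.log(2.0)


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    ``loading`` is the gene-to-latent-factor correlation on the log2 scale;
    member-member correlations are therefore approximately ``loading**2``.
    ``trait_cor`` links the module's latent factor to a continuous clinical
    trait named ``trait`` (0 = no linked trait).
    """

    size: int = 100
    loading: float = 0.8
    trait_cor: float = 0.0
    trait: Optional[str] = None


@dataclass
class PerturbationSpec:
    """Planted individual-level perturbations in LT samples.

    ``delta`` is the shift in units of the gene's log2-scale reference SD,
    so a perturbed gene is expected to score z ~ delta in a perturbation
    profile. Each LT sample gets ``n_private`` genes of its own; each of
    ``n_shared`` genes is planted in ``share_k`` LT samples.
    """

    n_private: int = 30
    n_shared: int = 10
    share_k: int = 5
    delta: float = 4.0


@dataclass
class NetworkSpec:
    n_nodes: int = 2000
    m: int = 10
    planted_neighborhood: int = 60
    n_seed_genes: int = 6
    internal_edge_prob: float = 0.25


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_st: int = 10
    n_lt: int = 9
    # per-gene baseline mean counts ~ LogNormal(mean_log_mu, mean_log_sigma)
    mean_log_mu: float = 4.0
    mean_log_sigma: float = 1.5
    # per-gene NB dispersion ~ Gamma(shape, scale); variance = mu + a*mu^2
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    # planted group-level DEGs
    n_deg: int = 50
    lfc_range: tuple[float, float] = (2.5, 4.0)
    # planted co-expression modules
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(100, 0.8, 0.8, "biomarker"),
            ModuleSpec(100, 0.8),
            ModuleSpec(100, 0.8),
            ModuleSpec(100, 0.8),
            ModuleSpec(100, 0.8),
        ]
    )
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    # planted effects are placed on genes whose baseline mean count is at
    # least this, so they act on genes the assay can actually measure
    min_planted_mean: float = 20.0
    # library-size factors ~ LogNormal(0, size_factor_sigma), clipped to [0.5, 2]
    size_factor_sigma: float = 0.25
    # survival: ST ~ U(3, 12); LT ~ 36 + Exponential(lt_surv_scale)
    lt_surv_scale: float = 12.0
    lt_event_prob: float = 0.5
    # optional planted prognostic genes (expression-linked hazard)
    n_prognostic: int = 0
    prognostic_hr_per_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total_planted = (
            self.n_deg
            + sum(m.size for m in self.modules)
            + self.n_lt * self.perturbation.n_private
            + self.perturbation.n_shared
            + self.n_prognostic
        )
        if total_planted > self.n_genes:
            raise ConfigError(
                f"planted gene sets need {total_planted} genes but n_genes={self.n_genes}"
            )
        if self.perturbation.delta <= 0:
            raise ConfigError("perturbation delta must be > 0")
        if not (0 < self.perturbation.share_k <= self.n_lt):
            raise ConfigError("share_k must be in 1..n_lt")
        # network nodes are drawn from the cohort's genes
        if self.network.n_nodes > self.n_genes:
            self.network.n_nodes = self.n_genes
            self.network.m = min(self.network.m, max(1, self.n_genes // 20))
            self.network.planted_neighborhood = min(
                self.network.planted_neighborhood, max(1, self.n_genes // 20)
            )
            self.network.n_seed_genes = min(
                self.network.n_seed_genes, self.network.planted_neighborhood
            )
        if self.network.planted_neighborhood > self.network.n_nodes:
            raise ConfigError("planted neighborhood larger than the network")


@dataclass
class GroundTruth:
    """Everything needed to score downstream recovery without the config."""

    deg_signs: dict[str, int] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    module_traits: dict[int, str] = field(default_factory=dict)
    perturbed: dict[str, set[str]] = field(default_factory=dict)  # sample -> genes
    shared_genes: dict[str, set[str]] = field(default_factory=dict)  # gene -> samples
    prognostic_genes: list[str] = field(default_factory=list)
    neighborhood: set[str] = field(default_factory=set)
    seed_genes: list[str] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "deg_signs": self.deg_signs,
            "module_labels": self.module_labels,
            "module_traits": {str(k): v for k, v in self.module_traits.items()},
            "perturbed": {s: sorted(g) for s, g in self.perturbed.items()},
            "shared_genes": {g: sorted(s) for g, s in self.shared_genes.items()},
            "prognostic_genes": self.prognostic_genes,
            "neighborhood": sorted(self.neighborhood),
            "seed_genes": self.seed_genes,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            deg_signs={k: int(v) for k, v in d["deg_signs"].items()},
            module_labels={k: int(v) for k, v in d["module_labels"].items()},
            module_traits={int(k): v for k, v in d["module_traits"].items()},
            perturbed={s: set(g) for s, g in d["perturbed"].items()},
            shared_genes={g: set(s) for g, s in d["shared_genes"].items()},
            prognostic_genes=list(d["prognostic_genes"]),
            neighborhood=set(d["neighborhood"]),
            seed_genes=list(d["seed_genes"]),
            seed=int(d["seed"]),
        )


def _log2_sd(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Delta-method SD of log2(count) for NB(mu, alpha)."""
    return np.sqrt(1.0 / mu + alpha) / _LN2


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Simulate counts, clinical traits, and the planted ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_counts, rng_clin = [
        np.random.default_rng(s) for s in root.spawn(3)
    ]

    n_genes, n_st, n_lt = cfg.n_genes, cfg.n_st, cfg.n_lt
    n = n_st + n_lt
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"ST{i+1}" for i in range(n_st)] + [f"LT{i+1}" for i in range(n_lt)]
    lt_samples = sample_ids[n_st:]
    is_lt = np.array([False] * n_st + [True] * n_lt)

    # per-gene baseline and dispersion
    base_mean = rng_genes.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, n_genes)
    alpha = rng_genes.gamma(cfg.dispersion_shape, cfg.dispersion_scale, n_genes)
    s_log2 = _log2_sd(base_mean, alpha)

    # carve out disjoint planted gene sets
    pert = cfg.perturbation
    n_needed = (
        cfg.n_deg
        + sum(m.size for m in cfg.modules)
        + n_lt * pert.n_private
        + pert.n_shared
        + cfg.n_prognostic
    )
    eligible = np.flatnonzero(base_mean >= cfg.min_planted_mean)
    if eligible.size < n_needed:
        raise ConfigError(
            f"only {eligible.size} genes have baseline mean >= {cfg.min_planted_mean} "
            f"but {n_needed} planted genes are required"
        )
    pool = rng_genes.choice(eligible, size=n_needed, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    truth = GroundTruth(seed=cfg.seed)
    module_trait_values: dict[str, np.ndarray] = {}
    log2_mean = np.tile(np.log2(base_mean)[:, None], (1, n))

    # group-level DEGs (LT vs ST effect)
    deg_idx = take(cfg.n_deg)
    lfc = rng_genes.uniform(*cfg.lfc_range, size=cfg.n_deg)
    signs = rng_genes.choice([-1, 1], size=cfg.n_deg)
    for i, g_idx in enumerate(deg_idx):
        truth.deg_signs[gene_ids[g_idx]] = int(signs[i])
        log2_mean[g_idx, is_lt] += signs[i] * lfc[i]

    # planted co-expression modules; the latent factors are drawn jointly
    # and orthonormalized in-sample (QR of a centered Gaussian matrix) so
    # the planted partition is identifiable at this sample size
    if cfg.modules:
        raw_f = rng_genes.standard_normal((n, len(cfg.modules)))
        raw_f -= raw_f.mean(axis=0, keepdims=True)
        q_f, _ = np.linalg.qr(raw_f)
        factors = q_f * math.sqrt(n - 1)  # unit sample SD, zero sample corr
    for mod_no, mspec in enumerate(cfg.modules, start=1):
        midx = take(mspec.size)
        factor = factors[:, mod_no - 1]
        lam = mspec.loading
        # scale the factor so gene-factor correlation ~ loading given NB noise
        coef = s_log2[midx] * lam / math.sqrt(1.0 - lam**2)
        log2_mean[midx, :] += coef[:, None] * factor[None, :]
        for g_idx in midx:
            truth.module_labels[gene_ids[g_idx]] = mod_no
        if mspec.trait is not None and mspec.trait_cor != 0.0:
            truth.module_traits[mod_no] = mspec.trait
            rho = mspec.trait_cor
            noise = rng_genes.standard_normal(n)
            module_trait_values[mspec.trait] = rho * factor + math.sqrt(1 - rho**2) * noise

    # per-LT private perturbations
    for j, s in enumerate(lt_samples):
        pidx = take(pert.n_private)
        col = n_st + j
        shift = rng_genes.choice([-1, 1], size=pert.n_private) * pert.delta
        log2_mean[pidx, col] += shift * s_log2[pidx]
        truth.perturbed[s] = {gene_ids[g] for g in pidx}

    # shared perturbations: each gene planted in share_k LT samples
    sidx = take(pert.n_shared)
    for g_idx in sidx:
        carriers = rng_genes.choice(n_lt, size=pert.share_k, replace=False)
        sign = rng_genes.choice([-1, 1])
        gene = gene_ids[g_idx]
        truth.shared_genes[gene] = set()
        for c in carriers:
            log2_mean[g_idx, n_st + c] += sign * pert.delta * s_log2[g_idx]
            truth.shared_genes[gene].add(lt_samples[c])
            truth.perturbed.setdefault(lt_samples[c], set()).add(gene)

    # optional prognostic genes
    prog_idx = take(cfg.n_prognostic)
    truth.prognostic_genes = [gene_ids[g] for g in prog_idx]

    # library-size factors and NB sampling
    sf = np.clip(rng_counts.lognormal(0.0, cfg.size_factor_sigma, n), 0.5, 2.0)
    mu = sf[None, :] * np.exp2(log2_mean)
    r = 1.0 / np.maximum(alpha, 1e-12)  # NB size parameter
    p = r[:, None] / (r[:, None] + mu)
    counts = rng_counts.negative_binomial(r[:, None], p)
    expr = ExpressionMatrix(gene_ids, sample_ids, counts.astype(np.int64), "counts")

    # clinical table
    st_os = rng_clin.uniform(3.0, 12.0, n_st)
    lt_os = 36.0 + rng_clin.exponential(cfg.lt_surv_scale, n_lt)
    if cfg.n_prognostic and len(prog_idx):
        # proportional-hazards draw: high expression of planted prognostic
        # genes accelerates death within each group's time window
        z = np.log2(counts[prog_idx, :] / sf[None, :] + 1.0)
        z = (z - z.mean(axis=1, keepdims=True)) / np.maximum(z.std(axis=1, keepdims=True), 1e-12)
        risk = z.mean(axis=0)
        log_hr = math.log(cfg.prognostic_hr_per_sd)
        u = rng_clin.uniform(size=n)
        base = -np.log(u) / np.exp(log_hr * risk)
        st_os = 3.0 + 9.0 * (1 - np.exp(-base[:n_st]))
        lt_os = 36.0 + cfg.lt_surv_scale * base[n_st:]
    os_months = np.concatenate([st_os, lt_os])
    event = np.concatenate(
        [
            np.ones(n_st, dtype=int),
            (rng_clin.uniform(size=n_lt) < cfg.lt_event_prob).astype(int),
        ]
    )

    trait_cols: dict[str, np.ndarray] = {}
    trait_types: dict[str, str] = {}
    for name, vals in module_trait_values.items():
        trait_cols[name] = vals
        trait_types[name] = "continuous"
    # one binary trait is always present
    trait_cols["lesion_binary"] = (rng_clin.uniform(size=n) < 0.5).astype(int)
    trait_types["lesion_binary"] = "categorical"
    traits = pd.DataFrame(trait_cols, index=sample_ids)

    clinical = ClinicalTable(
        sample_ids,
        [GROUP_ST] * n_st + [GROUP_LT] * n_lt,
        os_months,
        event,
        traits,
        trait_types,
    )
    return expr, clinical, truth


def generate_network(
    n_nodes: int,
    m: int,
    planted_neighborhood: int,
    seed: int,
    gene_ids: Optional[list[str]] = None,
    n_seed_genes: int = 6,
    internal_edge_prob: float = 0.25,
    directed: bool = False,
) -> tuple[InteractionNetwork, GroundTruth]:
    """Preferential-attachment network with a densified planted neighborhood.

    The planted neighborhood is grown by breadth-first search from a random
    low-degree node (so it is connected) and its internal edge density is
    boosted by adding random internal edges with probability
    ``internal_edge_prob`` per missing pair. Seed genes are a random subset
    of the neighborhood. Node ids default to ``G00000``-style gene ids so
    they align with a generated cohort.
    """
    if not (n_nodes > m >= 1):
        raise ConfigError(f"need n_nodes > m >= 1, got n_nodes={n_nodes}, m={m}")
    if planted_neighborhood > n_nodes:
        raise ConfigError("planted neighborhood larger than the network")
    if n_seed_genes > planted_neighborhood:
        raise ConfigError("more seed genes than neighborhood members")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))

    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_nodes)]
    if len(gene_ids) < n_nodes:
        raise ConfigError("fewer gene ids than network nodes")

    # BFS-grow a connected neighborhood from a random non-hub start
    degs = dict(g.degree())
    order = sorted(g.nodes, key=lambda v: (degs[v], v))
    start = order[int(rng.integers(len(order) // 2))] if planted_neighborhood else None
    members: list[int] = []
    if planted_neighborhood:
        from collections import deque

        seen = {start}
        q = deque([start])
        while q and len(members) < planted_neighborhood:
            v = q.popleft()
            members.append(v)
            nbrs = sorted(g.neighbors(v))
            rng.shuffle(nbrs)
            for u in nbrs:
                if u not in seen:
                    seen.add(u)
                    q.append(u)
        # densify internal edges
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if not g.has_edge(a, b) and rng.uniform() < internal_edge_prob:
                    g.add_edge(a, b)

    node_ids = [gene_ids[i] for i in range(n_nodes)]
    edges = []
    for a, b in sorted(g.edges()):
        s, t = gene_ids[a], gene_ids[b]
        if directed and rng.uniform() < 0.5:
            s, t = t, s
        edges.append((s, t, 1.0))
    network = InteractionNetwork(node_ids, edges, directed=directed)

    member_genes = {gene_ids[i] for i in members}
    seed_pick = rng.choice(sorted(member_genes), size=n_seed_genes, replace=False)
    truth = GroundTruth(
        neighborhood=member_genes, seed_genes=sorted(seed_pick), seed=seed
    )
    return network, truth


def generate_confounded_network(
    n_nodes: int = 1000,
    m: int = 5,
    planted_size: int = 30,
    n_seed_genes: int = 5,
    n_hub_links: int = 3,
    seed: int = 0,
) -> tuple[InteractionNetwork, GroundTruth]:
    """Hub-confounded prioritization benchmark.

    A preferential-attachment graph supplies strong hubs; the planted
    neighborhood is drawn from the low-degree half of the graph and wired
    into one sparse connected component, and every seed gene is linked to
    ``n_hub_links`` of the top hubs. Raw diffusion from the seeds then
    concentrates on the hub decoys, while a degree-corrected ranking should
    recover the planted neighbors.
    """
    import networkx as nx

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    degs = dict(g.degree())
    low = sorted(g.nodes, key=lambda v: (degs[v], v))[: n_nodes // 2]
    planted = [int(v) for v in rng.choice(low, size=planted_size, replace=False)]
    for i in range(planted_size):  # ring keeps the neighborhood connected
        g.add_edge(planted[i], planted[(i + 1) % planted_size])
    for _ in range(planted_size):
        a, b = rng.choice(planted, 2, replace=False)
        g.add_edge(int(a), int(b))
    seeds = [int(v) for v in rng.choice(planted, size=n_seed_genes, replace=False)]
    hubs = sorted(g.nodes, key=lambda v: -degs[v])[:10]
    for s in seeds:
        for h in rng.choice(hubs, size=n_hub_links, replace=False):
            g.add_edge(int(s), int(h))
    ids = [f"G{i:05d}" for i in range(n_nodes)]
    net = InteractionNetwork(
        ids, [(ids[a], ids[b], 1.0) for a, b in sorted(g.edges())], directed=False
    )
    truth = GroundTruth(
        neighborhood={ids[p] for p in planted},
        seed_genes=sorted(ids[s] for s in seeds),
        seed=seed,
    )
    return net, truth


def generate_two_layer_benchmark(
    n_nodes: int = 500,
    m: int = 3,
    n_samples: int = 9,
    n_perturbed_per_sample: int = 5,
    n_degs: int = 10,
    seed: int = 0,
) -> tuple[InteractionNetwork, dict[str, list[str]], list[str], str]:
    """Directed benchmark with a planted intermediate node.

    One low-degree node is wired to receive an edge from every sample's
    perturbed genes and to send an edge to every group-level differential
    gene, so it lies on the short paths between the two diffusion layers.
    Returns (network, per-sample perturbed genes, group genes, the
    intermediate node id).
    """
    import networkx as nx

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    ids = [f"G{i:05d}" for i in range(n_nodes)]
    edges: dict[tuple[str, str], float] = {}
    for a, b in sorted(g.edges()):
        if rng.uniform() < 0.5:
            a, b = b, a
        edges[(ids[a], ids[b])] = 1.0
    degs = dict(g.degree())
    low = sorted(g.nodes, key=lambda v: (degs[v], v))[: n_nodes // 2]
    picks = rng.choice(low, size=1 + n_degs + n_samples * n_perturbed_per_sample, replace=False)
    intermediate = ids[picks[0]]
    group_genes = [ids[i] for i in picks[1 : 1 + n_degs]]
    per_sample: dict[str, list[str]] = {}
    c = 1 + n_degs
    for s in range(n_samples):
        genes = [ids[i] for i in picks[c : c + n_perturbed_per_sample]]
        c += n_perturbed_per_sample
        per_sample[f"LT{s+1}"] = genes
        for p in genes:
            edges[(p, intermediate)] = 1.0
    for d in group_genes:
        edges[(intermediate, d)] = 1.0
    net = InteractionNetwork(
        ids, [(s, t, w) for (s, t), w in edges.items()], directed=True
    )
    return net, per_sample, group_genes, intermediate


def generate_gene_sets(
    truth: GroundTruth,
    universe: list[str],
    n_decoy_sets: int = 20,
    size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted structure plus random decoy sets."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    sets: dict[str, GeneSet] = {}
    if truth.deg_signs:
        sets["planted_DEG"] = GeneSet("planted differential genes", frozenset(truth.deg_signs))
    modules: dict[int, set[str]] = {}
    for g, mod in truth.module_labels.items():
        modules.setdefault(mod, set()).add(g)
    for mod, genes in sorted(modules.items()):
        sets[f"planted_module_{mod}"] = GeneSet(f"planted module {mod}", frozenset(genes))
    for s, genes in sorted(truth.perturbed.items()):
        if genes:
            sets[f"planted_perturbed_{s}"] = GeneSet(
                f"planted perturbations in {s}", frozenset(genes)
            )
    lo, hi = size_range
    for d in range(n_decoy_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(k, len(universe)), replace=False)
        sets[f"decoy_{d:03d}"] = GeneSet("random decoy set", frozenset(members))
    return GeneSetCollection(sets)
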