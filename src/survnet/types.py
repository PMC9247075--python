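"""Core in-memory containers shared by every pipeline stage.

Gene and sample identifiers are opaque, case-sensitive strings; joins
between the expression matrix, the interaction network and gene-set
collections are exact-string matches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


SCALE_COUNTS = "counts"
SCALE_LOGNORM = "lognorm"

#: explicit missing-value token used in clinical tables on disk
NA_TOKEN = "NA"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``scale_tag`` is ``"counts"`` for raw non-negative integer counts and
    ``"lognorm"`` for log2-normalized expression.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = SCALE_COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale_tag not in (SCALE_COUNTS, SCALE_LOGNORM):
            raise FormatError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == SCALE_COUNTS and (self.values < 0).any():
            raise FormatError("counts matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx], self.scale_tag
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), self.sample_ids, self.values[idx, :], self.scale_tag
        )


GROUP_ST = "ST"
GROUP_LT = "LT"


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    ``traits`` holds additional columns keyed by name; ``trait_types`` flags
    each one ``"continuous"`` or ``"categorical"`` (ordinal traits are coded
    as integers and flagged categorical, so they are analysed rank-based).
    """

    sample_ids: list[str]
    group: list[str]
    os_months: np.ndarray
    event: np.ndarray
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        self.group = list(self.group)
        self.os_months = np.asarray(self.os_months, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if not (len(self.group) == len(self.os_months) == len(self.event) == n):
            raise FormatError("clinical table columns have inconsistent lengths")
        bad = sorted(set(self.group) - {GROUP_ST, GROUP_LT})
        if bad:
            raise FormatError(f"unknown group labels: {bad}")
        if (self.os_months[~np.isnan(self.os_months)] <= 0).any():
            raise FormatError("os_months must be > 0")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise FormatError("event indicator must be 0/1")
        if self.traits is None or len(self.traits) == 0:
            self.traits = pd.DataFrame(index=self.sample_ids)
        else:
            self.traits = self.traits.copy()
            self.traits.index = self.sample_ids
        missing = set(self.traits.columns) - set(self.trait_types)
        if missing:
            raise FormatError(f"trait columns without a type flag: {sorted(missing)}")
        for name, kind in self.trait_types.items():
            if kind not in ("continuous", "categorical"):
                raise FormatError(f"trait {name!r} has unknown type {kind!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == group]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": self.group,
                "os_months": self.os_months,
                "event": self.event,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        return pd.concat([df, self.traits], axis=1)


@dataclass
class InteractionNetwork:
    """Gene interaction graph; undirected networks store each edge once."""

    node_ids: list[str]
    edges: list[tuple[str, str, float]]
    directed: bool = False

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        _check_unique(self.node_ids, "node")
        nodes = set(self.node_ids)
        seen: set[tuple[str, str]] = set()
        canon: list[tuple[str, str, float]] = []
        for s, t, w in self.edges:
            if s == t:
                raise FormatError(f"self-loop on node {s!r}")
            if s not in nodes or t not in nodes:
                raise FormatError(f"edge endpoint not in node list: ({s!r}, {t!r})")
            if w < 0:
                raise FormatError(f"negative edge weight on ({s!r}, {t!r})")
            key = (s, t) if self.directed else (min(s, t), max(s, t))
            if key in seen:
                raise FormatError(f"duplicate edge ({s!r}, {t!r})")
            seen.add(key)
            canon.append((s, t, float(w)))
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.node_ids}
        for s, t, _ in self.edges:
            deg[s] += 1
            deg[t] += 1
        return deg


@dataclass
class GeneSet:
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the published analysis values."""

    seed: int = 0
    # differential expression
    log2fc_up: float = 2.0
    log2fc_down: float = -2.0
    deg_p_threshold: float = 0.05
    pseudocount: float = 1.0
    # perturbation profiling
    z_threshold: float = 2.0
    n_permutations: int = 500
    # survival screen
    survival_split: str = "median"  # or "tertile"
    # co-expression
    soft_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.85
    network_type: str = "unsigned"
    min_module_size: int = 30
    cut_height_quantile: float = 0.90
    merge_cut_height: float = 0.25
    # network prioritization
    restart_prob: float = 0.4
    top_fraction: float = 0.01
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 1000
    # biclustering
    bimax_min_rows: int = 2
    bimax_min_cols: int = 2
    jaccard_cut: float = 0.5

    def __post_init__(self) -> None:
        for name in ("restart_prob", "top_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("n_permutations", "min_module_size", "rwr_max_iter"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be a positive integer, got {v}")
        if self.survival_split not in ("median", "tertile"):
            raise ConfigError(f"unknown survival_split {self.survival_split!r}")
        if self.network_type not in ("unsigned", "signed"):
            raise ConfigError(f"unknown network_type {self.network_type!r}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["soft_powers"] = list(self.soft_powers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "soft_powers" in d:
            d["soft_powers"] = tuple(d["soft_powers"])
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RankedGeneList:
    """Prioritization output: genes in descending-score order.

    Ranks are 1..N with ties assigned the average rank.
    """

    gene_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    provenance: str = ""
    seed_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be in descending order")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"gene_id": self.gene_ids, "score": self.scores, "rank": self.ranks}
        )
        if self.seed_flags is not None:
            df["is_seed"] = self.seed_flags.astype(int)
        return df
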