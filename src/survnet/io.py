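"""Readers and writers for the on-disk formats.

All tabular formats are plain TSV with a ``.`` decimal separator. Lines
starting with ``#`` are metadata (the pipeline stamps its seed and
parameter values there) and are skipped by every reader. Writers produce a
canonical byte representation so that read -> write round-trips are stable.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml

from .types import (
    NA_TOKEN,
    SCALE_COUNTS,
    SCALE_LOGNORM,
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    RunConfig,
)

logger = logging.getLogger("survnet")

PathLike = Union[str, Path]


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float."""
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _metadata_lines(metadata: Optional[dict]) -> list[str]:
    if not metadata:
        return []
    return [f"# {k}={v}" for k, v in metadata.items()]


def _read_lines(path: PathLike) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            out.append((i, line))
    return out


# ---------------------------------------------------------------------------
# expression matrices


def read_counts(path: PathLike) -> ExpressionMatrix:
    """Read a TSV count matrix (header = sample ids, first column = gene ids)."""
    return _read_expression(path, SCALE_COUNTS)


def read_lognorm(path: PathLike) -> ExpressionMatrix:
    return _read_expression(path, SCALE_LOGNORM)


def _read_expression(path: PathLike, scale_tag: str) -> ExpressionMatrix:
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header_no, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise FormatError(f"{path}:{header_no}: header has no sample columns")
    sample_ids = cols[1:]
    seen = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}:{header_no}: duplicate sample id {s!r}")
        seen.add(s)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen_genes: set[str] = set()
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise FormatError(
                f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen_genes:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen_genes.add(gene)
        try:
            row = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        gene_ids.append(gene)
        rows.append(row)
    values = np.asarray(rows, dtype=float)
    if scale_tag == SCALE_COUNTS:
        if (values < 0).any():
            raise FormatError(f"{path}: negative values in a counts matrix")
        if np.all(values == np.floor(values)):
            values = values.astype(np.int64)
    return ExpressionMatrix(gene_ids, sample_ids, values, scale_tag)


def write_table(
    expr: ExpressionMatrix, path: PathLike, metadata: Optional[dict] = None
) -> None:
    lines = _metadata_lines(metadata)
    lines.append("\t".join(["gene_id"] + expr.sample_ids))
    integral = np.issubdtype(expr.values.dtype, np.integer)
    for g, row in zip(expr.gene_ids, expr.values):
        if integral:
            cells = [str(int(v)) for v in row]
        else:
            cells = [_fmt(v) for v in row]
        lines.append("\t".join([g] + cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# clinical tables


_CLINICAL_FIXED = ("sample_id", "group", "os_months", "event")


def read_clinical(path: PathLike) -> ClinicalTable:
    """Read a clinical TSV.

    The file may carry a ``#types`` line flagging each trait column
    ``continuous`` or ``categorical``; without one, numeric traits are
    inferred continuous and the rest categorical.
    """
    type_line: Optional[list[str]] = None
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#types\t"):
                type_line = raw.rstrip("\n").split("\t")[1:]
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty clinical file")
    header_no, header = lines[0]
    cols = header.split("\t")
    if tuple(cols[:4]) != _CLINICAL_FIXED:
        raise FormatError(
            f"{path}:{header_no}: header must start with {_CLINICAL_FIXED}"
        )
    trait_names = cols[4:]
    records: list[list[str]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise FormatError(
                f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
            )
        records.append(fields)
    sample_ids = [r[0] for r in records]
    group = [r[1] for r in records]

    def parse_num(v: str, lineno: str = "") -> float:
        if v == NA_TOKEN:
            return np.nan
        return float(v)

    os_months = np.array([parse_num(r[2]) for r in records])
    event = np.array([int(r[3]) for r in records])

    import pandas as pd

    traits = {}
    trait_types: dict[str, str] = {}
    for j, name in enumerate(trait_names):
        raw_col = [r[4 + j] for r in records]
        if type_line is not None and 3 + j < len(type_line):
            kind = type_line[3 + j]
        else:
            try:
                [parse_num(v) for v in raw_col]
                kind = "continuous"
            except ValueError:
                kind = "categorical"
        if kind == "continuous":
            traits[name] = [parse_num(v) for v in raw_col]
        else:
            traits[name] = [np.nan if v == NA_TOKEN else v for v in raw_col]
        trait_types[name] = kind
    traits_df = pd.DataFrame(traits, index=sample_ids)
    return ClinicalTable(sample_ids, group, os_months, event, traits_df, trait_types)


def write_clinical(
    clinical: ClinicalTable, path: PathLike, metadata: Optional[dict] = None
) -> None:
    lines = _metadata_lines(metadata)
    trait_names = list(clinical.traits.columns)
    if trait_names:
        lines.append(
            "#types\t" + "\t".join(
                ["-", "-", "-"] + [clinical.trait_types[t] for t in trait_names]
            )
        )
    lines.append("\t".join(list(_CLINICAL_FIXED) + trait_names))
    for i, s in enumerate(clinical.sample_ids):
        cells = [
            s,
            clinical.group[i],
            NA_TOKEN if np.isnan(clinical.os_months[i]) else _fmt(clinical.os_months[i]),
            str(int(clinical.event[i])),
        ]
        for t in trait_names:
            v = clinical.traits.iloc[i][t]
            if isinstance(v, float) and np.isnan(v):
                cells.append(NA_TOKEN)
            elif clinical.trait_types[t] == "continuous":
                cells.append(_fmt(float(v)))
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# networks


def read_network(path: PathLike, directed: bool = False) -> InteractionNetwork:
    """Read an edge-list TSV (``source\\ttarget[\\tweight]``) or a SIF file.

    SIF format (``source relation target``, whitespace-separated) is used
    when the file name ends in ``.sif``. Self-loops are dropped with a
    logged count; the default edge weight is 1.0.
    """
    is_sif = str(path).endswith(".sif")
    lines = _read_lines(path)
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    node_seen: set[str] = set()
    edge_seen: set[tuple[str, str]] = set()
    dropped_loops = 0

    def add_node(n: str) -> None:
        if n not in node_seen:
            node_seen.add(n)
            nodes.append(n)

    for lineno, line in lines:
        if is_sif:
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: SIF line needs source, relation, target(s)"
                )
            src, targets, weight = fields[0], fields[2:], 1.0
        else:
            fields = line.split("\t")
            if len(fields) == 2:
                src, targets, weight = fields[0], [fields[1]], 1.0
            elif len(fields) == 3:
                try:
                    weight = float(fields[2])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
                src, targets = fields[0], [fields[1]]
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
        add_node(src)
        for tgt in targets:
            add_node(tgt)
            if src == tgt:
                dropped_loops += 1
                continue
            key = (src, tgt) if directed else (min(src, tgt), max(src, tgt))
            if key in edge_seen:
                continue
            edge_seen.add(key)
            edges.append((src, tgt, weight))
    if dropped_loops:
        logger.info("read_network: dropped %d self-loop(s) from %s", dropped_loops, path)
    return InteractionNetwork(nodes, edges, directed=directed)


def write_network(
    network: InteractionNetwork, path: PathLike, metadata: Optional[dict] = None
) -> None:
    lines = _metadata_lines(metadata)
    for s, t, w in network.edges:
        lines.append(f"{s}\t{t}\t{_fmt(w)}")
    # isolated nodes are preserved as degenerate single-field lines? No:
    # the edge-list format cannot carry them; they are recorded in metadata.
    isolated = [n for n, d in network.degrees().items() if d == 0]
    if isolated:
        lines.insert(0, f"# isolated_nodes={','.join(isolated)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# gene sets and gene lists


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = GeneSet(desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    lines = []
    for name, gs in collection:
        lines.append("\t".join([name, gs.description] + sorted(gs.members)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_list(path: PathLike) -> list[str]:
    """One gene id per line; duplicates rejected."""
    genes: list[str] = []
    seen: set[str] = set()
    for lineno, line in _read_lines(path):
        g = line.strip()
        if g in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {g!r}")
        seen.add(g)
        genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration and summaries


def read_run_config(path: PathLike) -> RunConfig:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.from_dict(data)


def write_run_config(cfg: RunConfig, path: PathLike) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(
            json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True), encoding="utf-8")


def write_json_summary(data: dict, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_dataframe(df, path: PathLike, metadata: Optional[dict] = None) -> None:
    """Write a pandas DataFrame as TSV with an optional metadata header."""
    header = "".join(line + "\n" for line in _metadata_lines(metadata))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", na_rep=NA_TOKEN)
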