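"""Evidence integration across analysis streams and the end-to-end driver.

``evidence_matrix`` lines up, per gene, the group-level differential call,
membership of a clinically significant co-expression module, the
individual-level perturbation sharing count, and presence in the top
fraction of the two network prioritizations, plus the Venn counts of
every pairwise intersection and the (DEG, clinical module, PEEP) triple.
No combined meta-score is imposed; an optional sum-of-flags ordering is
provided as a clearly heuristic convenience.

``run_pipeline`` executes the whole synthetic-cohort analysis
(simulate -> normalize -> DEG -> survival screen -> PEEP (+ permutation
null) -> co-expression modules (+ trait association) -> degree-aware and
two-layer prioritization -> biclustering -> evidence matrix) and, because
the generator plants ground truth, scores every stage's recovery in the
run summary.
"""
from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as sio
from .coexpression import (
    detect_modules,
    filter_constant_genes,
    merge_modules,
    module_significance,
    module_trait_association,
    pick_soft_threshold,
    tom_from_expression,
)
from .group_level import differential_expression, normalize_log, size_factors, survival_screen
from .network_prior import degree_aware_rank, top_fraction, two_layer_rank
from .patterns import bimax, hypergeom_enrichment, jaccard_superclusters
from .peep import peep_from_cohort, permutation_null, sharing_frequency
from .simulate import SimulationConfig, generate_cohort, generate_gene_sets, generate_network
from .types import RunConfig

logger = logging.getLogger("survnet")


def evidence_matrix(
    universe: Sequence[str],
    deg_table: pd.DataFrame,
    module_labels: Mapping[str, int],
    significant_modules: Sequence[int],
    peep_sharing: Mapping[str, int],
    dada_top: Sequence[str],
    netics_top: Sequence[str],
    max_mismatch: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene evidence table and Venn counts across the streams."""
    universe = list(universe)
    uni = set(universe)
    streams = {
        "deg": set(deg_table.index[deg_table["direction"] != "ns"]) if len(deg_table) else set(),
        "clinical_module": {
            g for g, m in module_labels.items() if m in set(significant_modules)
        },
        "peep": {g for g, c in peep_sharing.items() if c >= 1},
        "dada_top": set(dada_top),
        "netics_top": set(netics_top),
    }
    outside = set().union(*streams.values()) - uni
    if len(uni) and len(outside) > max_mismatch * len(uni):
        raise ValueError(
            f"{len(outside)} evidence genes absent from the {len(uni)}-gene universe "
            f"(> {max_mismatch:.0%}); identifier namespaces probably differ"
        )

    deg_dir = deg_table["direction"] if len(deg_table) else pd.Series(dtype=object)
    rows = []
    for g in universe:
        rows.append(
            {
                "gene_id": g,
                "is_deg": int(g in streams["deg"]),
                "deg_direction": deg_dir.get(g, "ns"),
                "clinical_module": module_labels.get(g, 0)
                if g in streams["clinical_module"]
                else 0,
                "peep_sharing": int(peep_sharing.get(g, 0)),
                "in_dada_top": int(g in streams["dada_top"]),
                "in_netics_top": int(g in streams["netics_top"]),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    df["evidence_count"] = (
        df["is_deg"]
        + (df["clinical_module"] > 0).astype(int)
        + (df["peep_sharing"] > 0).astype(int)
        + df["in_dada_top"]
        + df["in_netics_top"]
    )

    venn: dict[str, int] = {}
    for a, b in itertools.combinations(streams, 2):
        venn[f"{a}&{b}"] = len(streams[a] & streams[b])
    # full 8-cell partition of the (deg, clinical_module, peep) triple
    d, c, p = streams["deg"], streams["clinical_module"], streams["peep"]
    triple = {}
    for in_d, in_c, in_p in itertools.product((0, 1), repeat=3):
        cell = uni.copy()
        for flag, s in ((in_d, d), (in_c, c), (in_p, p)):
            cell = cell & s if flag else cell - s
        triple["".join(f"{n}={v}" for n, v in zip("dcp", (in_d, in_c, in_p)))] = len(cell)
    counts = {
        "stream_sizes": {k: len(v) for k, v in streams.items()},
        "pairwise": venn,
        "triple_deg_module_peep": triple,
    }
    return df, counts


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    summary: dict
    out_dir: Optional[Path] = None
    artifacts: dict = field(default_factory=dict)


def _score_recovery(found: set[str], truth: set[str]) -> dict:
    tp = len(found & truth)
    return {
        "n_found": len(found),
        "n_true": len(truth),
        "true_positives": tp,
        "sensitivity": tp / len(truth) if truth else np.nan,
        "precision": tp / len(found) if found else np.nan,
    }


def run_pipeline(
    sim_cfg: Optional[SimulationConfig] = None,
    run_cfg: Optional[RunConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full analysis on a simulated cohort and score it against truth."""
    sim_cfg = sim_cfg or SimulationConfig()
    run_cfg = run_cfg or RunConfig(seed=sim_cfg.seed)
    t0 = time.time()
    meta = {"seed": run_cfg.seed, **{k: v for k, v in run_cfg.to_dict().items() if k != "seed"}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    artifacts: dict = {}
    summary: dict = {"config": run_cfg.to_dict(), "sim_seed": sim_cfg.seed}
    try:
        counts, clinical, truth = generate_cohort(sim_cfg)
        net_seed = int(np.random.SeedSequence(sim_cfg.seed).spawn(5)[3].generate_state(1)[0] % (2**31))
        network, net_truth = generate_network(
            sim_cfg.network.n_nodes,
            sim_cfg.network.m,
            sim_cfg.network.planted_neighborhood,
            seed=net_seed,
            gene_ids=counts.gene_ids,
            n_seed_genes=sim_cfg.network.n_seed_genes,
            internal_edge_prob=sim_cfg.network.internal_edge_prob,
        )
        truth.neighborhood = net_truth.neighborhood
        truth.seed_genes = net_truth.seed_genes
        gene_sets = generate_gene_sets(truth, counts.gene_ids, seed=sim_cfg.seed)
        artifacts.update(counts=counts, clinical=clinical, truth=truth, network=network)
        if out is not None:
            sio.write_table(counts, out / "counts.tsv", meta)
            sio.write_clinical(clinical, out / "clinical.tsv", meta)
            sio.write_network(network, out / "network.tsv", meta)
            sio.write_gmt(gene_sets, out / "sets.gmt")
            sio.write_json_summary(truth.to_dict(), out / "truth.json")

        stage = "normalize"
        sf = size_factors(counts)
        lognorm = normalize_log(counts, sf, run_cfg.pseudocount)

        stage = "differential_expression"
        deg = differential_expression(counts, clinical, run_cfg)
        deg_genes = set(deg.deg_genes)
        artifacts["deg"] = deg
        if out is not None:
            sio.write_dataframe(deg.table, out / "deg_table.tsv", meta)
        summary["deg"] = {
            **_score_recovery(deg_genes, set(truth.deg_signs)),
            "n_up": int((deg.table["direction"] == "up").sum()),
            "n_down": int((deg.table["direction"] == "down").sum()),
        }

        stage = "survival_screen"
        screen_genes = sorted(deg_genes) if deg_genes else []
        if screen_genes:
            surv = survival_screen(lognorm, clinical, screen_genes, run_cfg.survival_split)
            if out is not None:
                sio.write_dataframe(surv, out / "survival_screen.tsv", meta)
            summary["survival_screen"] = {
                "n_tested": int(surv["testable"].sum()),
                "n_prognostic": int(surv["prognostic"].sum()),
            }
            artifacts["survival"] = surv

        stage = "peep"
        profiles = peep_from_cohort(lognorm, clinical, run_cfg.z_threshold)
        null = permutation_null(
            lognorm, clinical, run_cfg.n_permutations, run_cfg.z_threshold, run_cfg.seed
        )
        per_gene, by_count = sharing_frequency(profiles.calls_frame())
        artifacts.update(peep=profiles, peep_null=null)
        if out is not None:
            sio.write_dataframe(profiles.z_frame().round(6), out / "peep_z.tsv", meta)
            sio.write_dataframe(profiles.calls_frame(), out / "peep_calls.tsv", meta)
            sio.write_dataframe(per_gene.to_frame(), out / "sharing.tsv", meta)
            sio.write_json_summary(null.to_dict(), out / "permutation_summary.json")
        peep_scores = {}
        for s in profiles.target_sample_ids:
            called = set(
                profiles.calls_frame().index[profiles.calls_frame()[s] == 1]
            )
            peep_scores[s] = _score_recovery(called, truth.perturbed.get(s, set()))
        shared_recovered = {
            g: int(per_gene.get(g, 0)) for g in truth.shared_genes
        }
        summary["peep"] = {
            "n_perturbed_total": int((per_gene > 0).sum()),
            "per_sample_counts": {
                s: int(c)
                for s, c in zip(profiles.target_sample_ids, profiles.per_sample_counts)
            },
            "per_sample_recovery": peep_scores,
            "mean_sensitivity": float(
                np.mean([v["sensitivity"] for v in peep_scores.values()])
            ),
            "shared_gene_observed_frequency": shared_recovered,
            "empirical_p": null.to_dict()["empirical_p"],
        }

        stage = "coexpression"
        coexpr = filter_constant_genes(lognorm)
        soft = pick_soft_threshold(
            coexpr, run_cfg.soft_powers, run_cfg.r2_target, run_cfg.network_type
        )
        tom = tom_from_expression(coexpr, soft.chosen, run_cfg.network_type)
        modules = detect_modules(
            1.0 - tom, coexpr.gene_ids, run_cfg.min_module_size, run_cfg.cut_height_quantile
        )
        modules = merge_modules(coexpr, modules, run_cfg.merge_cut_height)
        mt = module_trait_association(modules.eigengenes, clinical)
        sig_modules = sorted(
            int(m[2:]) for m in mt.loc[mt["significant"], "module"].unique()
        )
        artifacts.update(modules=modules, module_trait=mt, soft=soft)
        if out is not None:
            sio.write_dataframe(soft.to_frame(), out / "soft_threshold.tsv", meta)
            sio.write_dataframe(modules.labels_frame(), out / "module_labels.tsv", meta)
            sio.write_dataframe(modules.eigengenes.round(6), out / "eigengenes.tsv", meta)
            sio.write_dataframe(mt, out / "module_trait.tsv", meta)
        planted = [g for g in lognorm.gene_ids if g in truth.module_labels]
        label_map = dict(zip(modules.gene_ids, modules.labels))
        ari = (
            float(
                adjusted_rand_score(
                    [truth.module_labels[g] for g in planted],
                    [int(label_map.get(g, 0)) for g in planted],
                )
            )
            if planted
            else np.nan
        )
        trait_hits = {}
        for mod_no, trait in truth.module_traits.items():
            planted_members = {g for g, m in truth.module_labels.items() if m == mod_no}
            hit = False
            for m in sig_modules:
                sig_rows = mt[(mt["module"] == f"ME{m}") & mt["significant"] & (mt["trait"] == trait)]
                if len(sig_rows):
                    members = set(modules.members(m))
                    overlap = len(members & planted_members)
                    if overlap >= 0.5 * len(planted_members):
                        hit = True
            trait_hits[str(mod_no)] = hit
        summary["modules"] = {
            "soft_power": int(soft.chosen),
            "soft_power_reached_target": bool(soft.reached_target),
            "n_modules": len(modules.module_ids),
            "module_sizes": {str(k): v for k, v in modules.module_sizes().items()},
            "planted_ari": ari,
            "n_significant_module_trait_pairs": int(mt["significant"].sum()),
            "trait_linked_module_detected": trait_hits,
        }

        stage = "prioritize"
        dada = degree_aware_rank(
            network, truth.seed_genes, run_cfg.restart_prob, run_cfg.rwr_tol, run_cfg.rwr_max_iter
        )
        dada_top = top_fraction(dada, run_cfg.top_fraction)
        calls = profiles.calls_frame()
        per_sample_sets = {
            s: list(calls.index[calls[s] == 1]) for s in profiles.target_sample_ids
        }
        netics = two_layer_rank(
            network,
            per_sample_sets,
            sorted(deg_genes) or list(truth.deg_signs),
            run_cfg.restart_prob,
        )
        netics_top = top_fraction(netics, run_cfg.top_fraction)
        artifacts.update(dada=dada, netics=netics, dada_top=dada_top, netics_top=netics_top)
        if out is not None:
            sio.write_dataframe(dada.to_frame().set_index("gene_id"), out / "dada_ranked.tsv", meta)
            sio.write_dataframe(netics.to_frame().set_index("gene_id"), out / "netics_ranked.tsv", meta)
            sio.write_gene_list(dada_top, out / "dada_top.txt")
            sio.write_gene_list(netics_top, out / "netics_top.txt")
        summary["prioritize"] = {
            "dada": _score_recovery(set(dada_top), truth.neighborhood),
            "netics_top_size": len(netics_top),
        }

        stage = "patterns"
        call_mat = calls.to_numpy()
        active = call_mat.sum(axis=1) >= 2  # genes perturbed in >= 2 samples
        biclusters = bimax(
            call_mat[active], run_cfg.bimax_min_rows, run_cfg.bimax_min_cols
        )
        active_genes = [g for g, a in zip(calls.index, active) if a]
        cluster_sets = [
            frozenset(active_genes[i] for i in bc.rows) for bc in biclusters
        ]
        n_super = 0
        if len(cluster_sets) >= 2:
            _, _, super_labels = jaccard_superclusters(cluster_sets, run_cfg.jaccard_cut)
            n_super = int(super_labels.max())
        enr = hypergeom_enrichment(
            deg_genes or set(truth.deg_signs), gene_sets, set(counts.gene_ids), sided="one"
        )
        if out is not None:
            bc_rows = [
                {
                    "bicluster": i,
                    "n_genes": len(bc.rows),
                    "n_samples": len(bc.cols),
                    "samples": ",".join(profiles.target_sample_ids[j] for j in sorted(bc.cols)),
                    "genes": ",".join(sorted(active_genes[r] for r in bc.rows)),
                }
                for i, bc in enumerate(biclusters)
            ]
            sio.write_dataframe(
                pd.DataFrame(bc_rows).set_index("bicluster")
                if bc_rows
                else pd.DataFrame(columns=["n_genes"]),
                out / "biclusters.tsv",
                meta,
            )
            sio.write_dataframe(enr, out / "enrichment.tsv", meta)
        summary["patterns"] = {
            "n_biclusters": len(biclusters),
            "n_superclusters": n_super,
            "top_enriched_set": str(enr.index[0]) if len(enr) else None,
            "top_enrichment_p_adj": float(enr["p_adj"].iloc[0]) if len(enr) else None,
        }

        stage = "integrate"
        ev, venn = evidence_matrix(
            counts.gene_ids,
            deg.table,
            label_map,
            sig_modules,
            per_gene.to_dict(),
            dada_top,
            netics_top,
        )
        if out is not None:
            sio.write_dataframe(ev, out / "evidence_matrix.tsv", meta)
            sio.write_json_summary(venn, out / "venn_counts.json")
        summary["evidence"] = venn
        if out is not None:
            sio.write_json_summary(summary, out / "summary.json")
        result = PipelineResult(summary, out, artifacts)
        result.artifacts["runtime_seconds"] = round(time.time() - t0, 3)
        logger.info("run_pipeline: finished in %.1fs", time.time() - t0)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
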