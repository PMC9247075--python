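# survnet

Integrative transcriptome network analysis for two-group survival cohorts.

`survnet` addresses a question that comes up in small clinical RNA-seq
studies, prototypically pancreatic ductal adenocarcinoma (PDAC): given a
handful of **short-term (ST, overall survival ≤ 12 months)** and
**long-term (LT, ≥ 36 months)** survivors, which genes distinguish the
groups, and which genes matter only in *individual* patients? Group-level
statistics alone miss the pronounced patient-to-patient heterogeneity of
long-term survival, so the pipeline combines group- and individual-level
evidence with network context:

1. **Differential expression (LT vs ST)** — negative-binomial Wald test on
   median-of-ratios–normalized counts; genes called up/down at
   |log₂FC| ≥ 2 with unadjusted *p* < 0.05.
2. **Prognostic screening** — per-gene Kaplan–Meier curves split at the
   median expression, compared by the log-rank test.
3. **Perturbation expression profiles (PEEPs)** — per LT patient *j* and
   gene *i*, *z*ᵢⱼ = (*x*ᵢⱼ − μ̂ᵢ)/σ̂ᵢ against the ST reference group;
   |z| ≥ 2 flags the gene as perturbed in that individual. A permutation
   null (500 ST/LT label reshuffles) calibrates each patient's
   perturbed-gene count.
4. **Co-expression modules** — WGCNA-style: soft-thresholded adjacency
   |cor|^β with β chosen by the scale-free topology criterion (R² > 0.85),
   topological overlap matrix (TOM), average-linkage clustering of
   1 − TOM, module eigengenes (first principal component), eigengene-based
   module merging at dissimilarity 0.25, and Pearson/Spearman module–trait
   association with Bonferroni control.
5. **Network prioritization** — random walk with restart (restart
   probability 0.4) on a gene interaction network: a degree-corrected
   seeded ranking (seeded-walk score divided by the uniform-restart
   baseline, removing hub bias) and a per-patient two-layer bidirectional
   diffusion (forward from each patient's PEEP genes × reverse from the
   group DEGs, aggregated by median rank). The top 1 % of each ranking
   forms a candidate disease module.
6. **Biclustering and enrichment** — Bimax enumeration of all
   inclusion-maximal all-ones blocks of the binary PEEP-call matrix,
   Jaccard-similarity superclusters, and hypergeometric gene-set
   enrichment against user GMT collections.
7. **Evidence integration** — per-gene table and Venn counts across all
   streams (DEG, clinically significant module membership, PEEP sharing,
   both top-1 % lists).

Because real cohorts of this design are small and access-controlled, the
package ships a first-class **synthetic cohort generator** that plants
every structure the pipeline is supposed to find — DEGs, trait-correlated
co-expression modules, private and shared individual perturbations, a
scale-free interactome with a densified disease neighborhood — and scores
every stage against that ground truth.

## Worked example

```python
from survnet import SimulationConfig, RunConfig, run_pipeline

result = run_pipeline(SimulationConfig(seed=1), RunConfig(seed=1), "run/")
s = result.summary
print("DEG sensitivity:", s["deg"]["sensitivity"])
print("module ARI:", round(s["modules"]["planted_ari"], 3))
print("PEEP mean sensitivity:", round(s["peep"]["mean_sensitivity"], 3))
print("degree-aware top-1% precision:", s["prioritize"]["dada"]["precision"])
```

prints, for this seed,

```
DEG sensitivity: 0.98
module ARI: 0.97
PEEP mean sensitivity: 0.938
degree-aware top-1% precision: 0.85
```

meaning: 49 of the 50 planted differential genes were recalled at the
|log₂FC| ≥ 2, *p* < 0.05 thresholds; the five planted co-expression
modules were recovered with adjusted Rand index 0.97 against the planted
labels; on average 94 % of each LT patient's planted perturbations were
flagged at |z| ≥ 2; and 17 of the 20 genes in the degree-corrected top 1 %
belong to the planted disease neighborhood. `run/` then contains every
intermediate table (deg_table.tsv, peep_z.tsv, module_trait.tsv,
dada_ranked.tsv, evidence_matrix.tsv, …) plus `summary.json` with the full
ground-truth scoring.

The same pipeline is scriptable from the shell:

```bash
survnet run --seed 1 --out-dir run/          # everything at once
survnet simulate --seed 1 --out-dir sim/     # or stage by stage
survnet deg --counts sim/counts.tsv --clinical sim/clinical.tsv --out-dir run/
survnet peep --counts sim/counts.tsv --clinical sim/clinical.tsv --out-dir run/
survnet modules --counts sim/counts.tsv --clinical sim/clinical.tsv --out-dir run/
survnet prioritize --method dada --network sim/network.tsv --seeds sim/seeds.txt --out-dir run/
```

Real data drop in the same way: a TSV count matrix, a clinical table with
`group`/`os_months`/`event` plus trait columns, an edge-list or SIF
network, and GMT gene sets.

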