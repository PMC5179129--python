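# mirtfnet

Integrative miRNA / transcription-factor / gene regulatory-network analysis
for multi-stage tumor expression studies, with a planted-truth synthetic-data
generator that makes every stage of the pipeline testable end to end.

## The problem

Cancer progression studies profile mRNA and miRNA expression across disease
stages (e.g. normal tissue, primary tumor, metastasis) and ask which
transcription factors (TFs) and miRNAs drive the observed dysregulation.
A widely used integrative recipe answers this in five steps:

1. **Differential expression.** For each stage comparison, entities with
   |log2 fold change| > 1 and p < 0.05 (Benjamini–Hochberg adjusted) are the
   DEGs / DETFs / DEMs. The default statistic is an empirical-Bayes
   moderated t: per-entity residual variances s² are shrunk toward a prior
   fitted by moment matching of log s² to a scaled-F law,
   s̃² = (d₀s₀² + d·s²)/(d₀ + d), with d₀ extra degrees of freedom.
2. **Correlation-filtered edges.** Candidate regulator→target pairs from an
   interaction prior (TRANSFAC-like for TFs, TargetScan/miRanda/MirTarbase-like
   for miRNAs) are kept only between DE endpoints with |Pearson r| > 0.4
   (TF edges additionally p < 0.05); the sign gives activation/repression,
   |r| the edge weight.
3. **Integrated network and key elements.** TF and miRNA edge sets merge
   into one undirected stage network. Per node, degree and normalized
   betweenness centrality BC(v) = Σ σ_uw(v)/σ_uw ÷ ((n−1)(n−2)/2) are
   computed; nodes with z-scores > 2 on **both** metrics are key elements.
4. **Binding-site enrichment.** Each key TF's mean promoter binding-site
   count over its network targets is compared against resampled random DEG
   sets (10% of the eligible pool, R = 999) with a one-sided permutation p.
5. **Survival validation.** Tumor samples split at each key marker's median
   expression; Kaplan–Meier curves, restricted mean survival time (MST) and
   the log-rank test quantify the biochemical-recurrence difference.

Real runs of this recipe need external array data and licensed interaction
databases. `mirtfnet` implements the full recipe as a reusable library and
ships a **synthetic-data generator with planted ground truth** — planted
fold changes, regulons with exact population correlation ±ρ, hub regulators,
binding-site enrichment and expression-driven hazards — so recovery rates,
false-discovery rates and calibration are measurable exactly.

## Worked example

```python
from mirtfnet import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulate=SimulationConfig(seed=42), seed=42, out_dir="out")
results = run_pipeline(cfg)
rep = results["keynodes"]["primary_vs_normal"]
print(rep.loc[rep["is_key"]].to_string(index=False))
```

prints (seed 42):

```
  node  role  degree       bc  z_degree     z_bc  is_key
 TF001    TF      13 0.510885  4.854308 5.901453    True
 TF002    TF      15 0.417594  5.741849 4.741369    True
miR001 miRNA      13 0.270134  4.854308 2.907693    True
```

i.e. the three planted hub regulators — and only they — exceed z > 2 on
degree and betweenness, exactly mirroring a "3 key elements per stage"
network structure. The run directory contains every intermediate table
(DE, edges, networks in TSV/GraphML, key-node reports, enrichment,
survival) plus `manifest.json` with the narrowing counts
prior → DE-restricted candidates → correlation-passing edges.

The scripts in `examples/` walk through each capability (simulation,
differential expression, network/key elements, enrichment + survival, full
pipeline); each prints the numbers it computes and what they mean. A thin
CLI mirrors the stages:

```bash
mirtfnet simulate --seed 42 --out-dir simdata
mirtfnet de --expression simdata/expression.tsv --metadata simdata/metadata.tsv --out de.tsv
mirtfnet run-all --config config.yaml
```

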