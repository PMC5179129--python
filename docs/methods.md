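# Methods

## Statistical model of the pipeline

**Differential expression.** Expression is assumed normalized and
log2-scaled; the package never exponentiates. For a comparison of case
group (n₁ ≥ 2) vs control group (n₂ ≥ 2), the fold change is the group
mean difference and the default statistic is an empirical-Bayes moderated
t: per-entity pooled variances s² (d = n₁+n₂−2 df) are shrunk as
s̃² = (d₀s₀² + d·s²)/(d₀+d), where (d₀, s₀²) are fitted by moment matching
of log s² to a scaled-F law — the excess of var(log s²) over the
trigamma(d/2) sampling contribution identifies trigamma(d₀/2), inverted by
Newton iteration. The t reference distribution has d + d₀ df (normal when
d₀ = ∞, which happens when the variances are no more dispersed than
sampling noise alone). A plain pooled-variance t (`moderated=False`) is
the documented cross-check mode; the implementation was verified against
Bioconductor limma's `eBayes` on a frozen fixture (agreement to 1e-6 in t
and in the fitted prior). Selection is strict: |LFC| > 1 **and** p < 0.05,
on the BH-adjusted p by default. The wording of the source recipe is
ambiguous about raw vs adjusted p; `use_adjusted=False` reproduces the
literal raw-p reading. A zero-variance entity with zero fold change gets
t = 0, p = 1 and a `degenerate` flag. The design is a plain two-group
contrast (no covariates or pairing).

**Correlation edges.** Candidate prior edges are narrowed to DE endpoints
(TF edges need both endpoints DE; miRNA edges need a DEM regulator and a
DEG target), then filtered at |r| > 0.4. TF edges additionally require
p < 0.05 (t reference with n−2 df); miRNA edges carry no p filter because
the miRNA selection rule is stated on |r| alone — a `mirna_p_threshold`
argument adds one. No multiple-testing correction is applied to
correlation p-values by default (`adjust=True` adds BH). The sample
universe for each stage's correlations is the comparison's case + control
groups (primary+normal, metastatic+primary); this is a declared
convention, not an inference — `tumor_only=True` restricts to the case
group. Both positive and negative miRNA–target correlations are retained.

**Network and key elements.** Edge sets merge into a simple undirected
graph (duplicate (regulator, target) records keep the largest |r|;
regulation direction survives only as an edge attribute). Betweenness is
normalized by (n−1)(n−2)/2, the undirected NetworkAnalyzer convention, and
computed by the Brandes accumulation algorithm (networkx); an independent
brute-force shortest-path enumerator (`betweenness_bruteforce`, BFS path
counting, guarded at 15 nodes) serves as the exact test oracle. z-scores
use the population (n-denominator) SD over all nodes; a zero-spread metric
flags nothing. The default key rule is the intersection — both z-scores
> 2 — as the literal reading of "degree and betweenness"; `rule="either"`
implements the union reading, which published key tables cannot
distinguish. Report ordering: betweenness desc, degree desc, id asc.

**Binding-site enrichment.** One-sided permutation test on the mean
binding-site count per target gene (the "frequency" definition is
per-gene mean, labeled as such): observed mean over the key regulator's
network targets vs R = 999 random DEG sets of size round(0.10 · pool),
clamped to ≥ 1, drawn without replacement from the DEGs excluding the
regulator's own targets; p = (1 + #{null ≥ obs})/(R+1), never zero. Genes
absent from the prior for that regulator count 0 rather than being
dropped. With discrete counts the test is mildly conservative (ties at
the observed value), visible in the null rejection rate sitting slightly
below 0.05.

**Survival.** Tumor samples split at the marker's median: high = strictly
above, ties to the low group (this tie rule is what makes group sizes
reproducible). Kaplan–Meier curves and the log-rank test come from
lifelines; hand product-limit and O−E/V computations are the independent
test oracles. "MST" is the restricted mean survival time — the area under
the KM curve up to the largest observed time — the only well-defined KM
mean under right censoring. No covariate adjustment.

## The synthetic-data generator

The generator emulates a three-group tumor study (defaults: 28 normal,
98 primary, 13 metastatic — the cohort shape of the prostate-cancer series
this recipe is typically applied to) over 200 genes, 20 TFs and 30 miRNAs.

* **Expression** = baseline N(8, 1) + planted group effect + noise_sd · z,
  noise_sd = 0.5 log2 units. Entities planted DE in the primary-vs-normal
  comparison shift by ±2 in primary *and* metastatic samples (progression
  retains primary-stage changes, which keeps the two comparisons
  orthogonal); metastatic-vs-primary effects shift metastatic samples only.
* **Regulons.** Each true edge ties its target's noise to the regulator's:
  z_target = s·ρ·z_reg + √(1−ρ²)·z_own with ρ = 0.8, so the within-group
  population Pearson correlation is exactly s·ρ — recovery rates are
  analytically checkable. Each gene is the target of at most one true
  edge, which keeps that exactness. miRNA loadings are negative except a
  configurable 20% positive fraction (mimicking the indirect positive
  miRNA–target correlations real data show); TF loadings are positive
  except a 30% negative fraction. A target's planted DE sign equals the
  regulator's times the edge sign, so mean structure and latent factor
  agree in pooled-sample correlations.
* **Hubs.** Three regulators (two TFs, one miRNA) with out-degree 12 —
  3× the mean background prior out-degree (prior density 0.02 over 200
  genes) — plus 20 single-target true edges as connective background.
* **Prior.** True edges always present; decoys sampled at density 0.02;
  binding-site counts are 1 + Poisson(mean−1) with mean 5 on true edges
  vs 1 on decoys.
* **Survival.** Exponential event times, log hazard = log(λ₀) +
  hazard_coef · x̄, λ₀ = ln2/60 per month (median ≈ 60 months at baseline),
  hazard_coef = 1 per log2 unit, x̄ = mean centered expression of the risk
  entities (default: the hubs). Censoring is an independent Bernoulli(0.3)
  that reports a uniform time before the event.
* **Determinism.** All randomness flows from `seed` through fixed
  per-artifact offsets (plan, prior, expression, survival), so
  regenerating one table never shifts the others; identical configs give
  byte-identical written tables.

What the generator does **not** emulate: probe-level noise, batch
effects, heavy-tailed or correlated background expression, realistic
regulon overlap (shared targets), copy-number/mutation layers. Passing
recovery tests therefore demonstrates the pipeline's correctness under
its own model assumptions, not performance on real arrays.

One emergent — and realistic — feature: over a pooled case+control sample
universe, *any* two DE entities correlate strongly through the shared
group-mean structure, so decoy prior edges between DE entities pass the
|r| > 0.4 filter. This is the same reason the recipe finds hundreds of
passing pairs on real data. It occasionally (≈1% of stage networks) lifts
a decoy regulator past both z-thresholds; recovery tests therefore bound
the *average* false-key count per network.

## Numerical and scale choices

* Trigamma inversion: Newton iteration on the transformed scale with
  asymptotic starts (1/√y for large y, 1/y for small), 50-iteration cap,
  relative tolerance 1e-10.
* Betweenness oracle equivalence is asserted to 1e-12 absolute on graphs
  of ≤ 12 nodes.
* Null-calibration and recovery tests use a scaled design (200 genes /
  20 TFs / 30 miRNAs, 30+30+13 samples for null runs) with 50 seeds, and
  Monte-Carlo bands of 3 binomial SEs around nominal rates; these sizes
  keep the whole suite fast while leaving the bands tight enough to catch
  real miscalibration.
* Survival times are floored at 1e-6 months to keep them strictly
  positive after uniform censoring.

## Known limitations

* The moderated-t prior fit uses plain moment matching (no robust
  down-weighting of outlier variances, no trend on average intensity).
* Betweenness is computed on the undirected graph; directed centralities
  are out of scope.
* The permutation test is conservative under heavy count ties.
* Survival validation is unadjusted KM/log-rank; no Cox model, no
  competing risks.
* With a polygenic hazard (several risk entities), single-marker median
  splits attenuate the detectable effect, and stage-DE markers can show
  residual survival associations through tumor-stage confounding — both
  visible in the examples and inherent to the median-split design.
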