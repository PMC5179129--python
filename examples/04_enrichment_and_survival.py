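"""Binding-site enrichment of hubs and survival validation of key markers.

Enrichment compares each hub's mean binding-site count on its targets
against 999 random DEG sets (10% of the eligible pool each); the planted
5-vs-1 means should give permutation p = 0.001.  For the survival stage
the hazard here is driven by a single hub (TF001, log HR = 1 per log2
unit), so splitting tumor samples at that hub's median expression shows a
clear relapse difference, while the other hubs act as negative controls.
"""

from mirtfnet import (
    SimulationConfig, bs_enrichment, generate_expression, generate_priors,
    generate_survival, random_deg_sets, survival_by_median_expression,
)
from mirtfnet.simulate import planted_truth

cfg = SimulationConfig(seed=42, risk_entities=("TF001",))
prior = generate_priors(cfg)
expr, meta, truth = generate_expression(cfg, prior)
surv = generate_survival(expr, meta, truth, cfg)

degs = {e for e in truth.de_set("primary_vs_normal") if e.startswith("G")}
for hub in sorted(truth.hub_nodes):
    targets = truth.edges_of(hub)
    null_sets = random_deg_sets(degs, targets, fraction=0.10, n_sets=999, seed=42)
    enr = bs_enrichment(hub, targets, prior, null_sets)
    res = survival_by_median_expression(expr, surv, hub)
    print(f"{hub}: BS mean {enr.observed_mean:.2f} vs null {enr.null_mean:.2f} "
          f"(perm p = {enr.perm_p:.3f}); "
          f"MST high/low = {res['high'].mst:.1f}/{res['low'].mst:.1f} months "
          f"(log-rank p = {res['logrank_p']:.4f})")
# perm p = 0.001 is the smallest value 999 resamples allow.  TF001, the
# planted hazard driver, shows a large MST gap with a small log-rank p.
# The other hubs do not drive the hazard; any residual association they
# show reflects shared tumor-stage structure (every stage-DE entity shifts
# in metastatic samples, and so does the hazard driver).
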