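"""Binding-site enrichment of key TFs against random DEG sets.

For a key TF, the mean promoter binding-site count over its correlated
network targets is compared with the means over resampled random sets of
differentially expressed genes (10% of the eligible DEG pool per set,
excluding the TF's own well-correlated targets).  Significance is a
one-sided permutation p-value with the add-one rule, so it is never
exactly zero.  Genes absent from the prior for a TF contribute a count of
0 rather than being dropped, which keeps set sizes honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BSEnrichmentResult:
    tf: str
    n_targets: int
    observed_mean: float
    null_means: np.ndarray
    ratio: float
    perm_p: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_means))


def random_deg_sets(
    degs: set[str],
    exclude: set[str],
    fraction: float = 0.10,
    n_sets: int = 999,
    seed: int = 0,
) -> list[list[str]]:
    """Without-replacement random DEG sets from the eligible pool.

    The pool is ``degs`` minus ``exclude`` (the key TF's correlated
    targets); each of the ``n_sets`` samples has size
    round(fraction * pool size), clamped to at least 1.
    """
    pool = sorted(degs - exclude)
    if not pool:
        raise ValueError("eligible DEG pool is empty after exclusion")
    size = max(1, round(fraction * len(pool)))
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    return [
        list(rng.choice(pool_arr, size=size, replace=False)) for _ in range(n_sets)
    ]


def binding_site_counts(prior: pd.DataFrame, tf: str) -> dict[str, int]:
    """Per-target binding-site counts of one TF from the prior table."""
    rows = prior.loc[prior["regulator"] == tf]
    return dict(zip(rows["target"], rows["binding_site_count"].astype(int)))


def bs_enrichment(
    tf: str,
    targets: set[str],
    prior: pd.DataFrame,
    null_sets: list[list[str]],
) -> BSEnrichmentResult:
    """Permutation enrichment of the TF's binding sites on its targets.

    observed_mean is the mean count over ``targets``; each null set yields
    one null mean; perm_p = (1 + #{null >= observed}) / (R + 1) one-sided.
    """
    if not targets:
        raise ValueError(f"empty target set for TF {tf!r}")
    counts = binding_site_counts(prior, tf)
    observed = float(np.mean([counts.get(g, 0) for g in sorted(targets)]))
    null_means = np.array(
        [np.mean([counts.get(g, 0) for g in s]) for s in null_sets], dtype=float
    )
    r = len(null_sets)
    perm_p = (1.0 + float(np.sum(null_means >= observed))) / (r + 1.0)
    nm = float(np.mean(null_means)) if r else np.nan
    ratio = observed / nm if nm and nm > 0 else (0.0 if observed == 0 else np.inf)
    return BSEnrichmentResult(
        tf=tf,
        n_targets=len(targets),
        observed_mean=observed,
        null_means=null_means,
        ratio=ratio,
        perm_p=perm_p,
    )


def enrich_key_tfs(
    key_report: pd.DataFrame,
    edges: pd.DataFrame,
    degs: set[str],
    prior: pd.DataFrame,
    fraction: float = 0.10,
    n_sets: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Binding-site enrichment for every key regulator in a stage network.

    Targets are the regulator's correlation-passing network targets; the
    null pool excludes them.  Returns a tidy table (tf, n_targets,
    observed_mean, null_mean, ratio, perm_p, n_resamples, seed).
    """
    rows = []
    key_regs = key_report.loc[
        key_report["is_key"] & key_report["role"].isin(["TF", "miRNA"]), "node"
    ]
    for i, tf in enumerate(key_regs):
        targets = set(edges.loc[edges["regulator"] == tf, "target"])
        if not targets:
            continue
        null_sets = random_deg_sets(
            degs, exclude=targets, fraction=fraction, n_sets=n_sets, seed=seed + i
        )
        res = bs_enrichment(tf, targets, prior, null_sets)
        rows.append(
            (
                tf,
                res.n_targets,
                res.observed_mean,
                res.null_mean,
                res.ratio,
                res.perm_p,
                n_sets,
                seed + i,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tf",
            "n_targets",
            "observed_mean",
            "null_mean",
            "ratio",
            "perm_p",
            "n_resamples",
            "seed",
        ],
    )
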