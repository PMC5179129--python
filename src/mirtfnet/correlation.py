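"""Correlation-based pruning of candidate regulator->target edges.

Prior candidate pairs are first narrowed to differentially expressed
endpoints (a TF edge needs both TF and target DE; a miRNA edge needs the
miRNA among the DE miRNAs and the target among the DE genes), then
filtered on the Pearson correlation of the two expression profiles over a
chosen sample set.  Surviving edges carry the correlation as weight and
its sign as activation (+) / repression (-).

Default thresholds: |r| > 0.4 for every edge, plus p < 0.05 for TF edges
only (the miRNA selection rule is stated on |r| alone).  No multiple-
testing correction is applied to correlation p-values by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EDGE_COLUMNS = [
    "regulator",
    "regulator_type",
    "target",
    "pcc",
    "p_value",
    "sign",
    "weight",
]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t reference, n - 2 df).

    Raises for unequal lengths, n < 3 or a constant vector (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def candidate_pairs(
    prior: pd.DataFrame,
    de_sets_by_comparison: dict[str, dict[str, set[str]]],
    comparison: str,
) -> pd.DataFrame:
    """Prior rows whose endpoints are differentially expressed.

    TF rows survive when both the TF and the target gene are DE in the
    comparison; miRNA rows when the miRNA is a DE miRNA and the target a
    DE gene.
    """
    if comparison not in de_sets_by_comparison:
        raise ValueError(f"unknown comparison {comparison!r}")
    sets = de_sets_by_comparison[comparison]
    deg = sets["gene"]
    is_tf = prior["regulator_type"] == "TF"
    keep_tf = is_tf & prior["regulator"].isin(sets["TF"]) & prior["target"].isin(deg)
    keep_mir = (
        (prior["regulator_type"] == "miRNA")
        & prior["regulator"].isin(sets["miRNA"])
        & prior["target"].isin(deg)
    )
    return prior.loc[keep_tf | keep_mir].reset_index(drop=True)


def filter_pairs(
    candidates: pd.DataFrame,
    expr: pd.DataFrame,
    samples: list[str],
    r_threshold: float = 0.4,
    tf_p_threshold: float | None = 0.05,
    mirna_p_threshold: float | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Correlation filter on candidate edges over the given samples.

    Keeps edges with |r| strictly greater than ``r_threshold``; TF edges
    are additionally required to have p < ``tf_p_threshold`` (default
    0.05) and miRNA edges p < ``mirna_p_threshold`` (default: no p filter).
    ``adjust=True`` applies BH across all candidate p-values first.
    Returns an edge table with pcc, p, sign (+1 activation / -1
    repression) and weight = |pcc|.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    missing = (set(candidates["regulator"]) | set(candidates["target"])) - set(expr.index)
    if missing:
        raise ValueError(f"candidate endpoints absent from expression: {sorted(missing)[:5]}")

    if candidates.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    sub = expr[samples]
    rows = []
    for reg, rtype, target in candidates[["regulator", "regulator_type", "target"]].itertuples(index=False):
        r, p = pearson(sub.loc[reg].to_numpy(), sub.loc[target].to_numpy())
        rows.append((reg, rtype, target, r, p))
    edges = pd.DataFrame(rows, columns=["regulator", "regulator_type", "target", "pcc", "p_value"])

    if adjust:
        from .diffexpr import adjust_bh

        edges["p_value"] = adjust_bh(edges["p_value"].to_numpy())

    keep = edges["pcc"].abs() > r_threshold
    is_tf = edges["regulator_type"] == "TF"
    if tf_p_threshold is not None:
        keep &= ~is_tf | (edges["p_value"] < tf_p_threshold)
    if mirna_p_threshold is not None:
        keep &= is_tf | (edges["p_value"] < mirna_p_threshold)

    out = edges.loc[keep].copy()
    out["sign"] = np.sign(out["pcc"]).astype(int)
    out["weight"] = out["pcc"].abs()
    return out[EDGE_COLUMNS].reset_index(drop=True)


def comparison_sample_universe(
    meta: pd.DataFrame, comparison_name: str, tumor_only: bool = False
) -> list[str]:
    """Samples over which edge correlations are computed for a stage.

    Default: case + control groups of the comparison (primary + normal for
    the primary stage; metastatic + primary for the metastatic stage);
    ``tumor_only=True`` restricts to the case group.
    """
    by_stage = {
        "primary_vs_normal": (["primary"], ["primary", "normal"]),
        "metastatic_vs_primary": (["metastatic"], ["metastatic", "primary"]),
    }
    if comparison_name not in by_stage:
        raise ValueError(f"unknown comparison {comparison_name!r}")
    case_only, both = by_stage[comparison_name]
    groups = case_only if tumor_only else both
    return meta.loc[meta["group"].isin(groups), "sample"].tolist()
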