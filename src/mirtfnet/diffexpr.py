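"""Two-group differential expression with empirical-Bayes moderated t.

Expression is assumed already normalized and on the log2 scale; fold
changes are therefore plain group-mean differences and nothing here ever
exponentiates.  The default statistic is a moderated t in the empirical-
Bayes style used for microarray linear models: per-entity residual
variances are shrunk toward a common prior fitted by moment matching of
log s^2 to a scaled-F law, and the t reference distribution gains the
estimated prior degrees of freedom.  A plain pooled-variance t is available
as the cross-check mode (``moderated=False``).

Selection follows the conventional microarray rule: |log2 fold change|
strictly greater than 1 and the chosen p-column strictly below 0.05, with
Benjamini-Hochberg adjustment applied across entities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .simulate import entity_role

RESULT_COLUMNS = [
    "entity",
    "role",
    "comparison",
    "lfc",
    "t_stat",
    "p_value",
    "adj_p",
    "is_de",
    "direction",
    "degenerate",
]


@dataclass(frozen=True)
class Comparison:
    """A named case-vs-control contrast between two sample groups."""

    name: str
    case_group: str
    control_group: str

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ValueError("case and control groups must differ")


#: the two stage contrasts of tumor progression
DEFAULT_COMPARISONS = (
    Comparison("primary_vs_normal", "primary", "normal"),
    Comparison("metastatic_vs_primary", "metastatic", "primary"),
)


def _group_samples(meta: pd.DataFrame, group: str) -> list[str]:
    samples = meta.loc[meta["group"] == group, "sample"].tolist()
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 2")
    return samples


def fit_fdist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the prior (d0, s0^2) of a scaled-F law to sample variances.

    Moment matching on z = log(s2): the excess variance of z over the
    trigamma(df/2) sampling contribution identifies trigamma(d0/2).
    Returns ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the
    observed variances are no more dispersed than pure sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the transformed scale (stable for small/large y)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_two_group(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    comparison: Comparison,
    moderated: bool = True,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-entity log2 fold change, (moderated) t and two-sided p.

    ``prior_df`` overrides the fitted prior degrees of freedom (0 recovers
    the plain pooled t; ``inf`` collapses all variances to the common
    prior) and is mainly useful for diagnostics.

    A zero-variance entity with zero fold change gets t = 0, p = 1 and is
    flagged in the ``degenerate`` column.
    """
    for group in (comparison.case_group, comparison.control_group):
        if group not in set(meta["group"]):
            raise ValueError(f"group {group!r} not present in sample metadata")
    case = _group_samples(meta, comparison.case_group)
    control = _group_samples(meta, comparison.control_group)

    x1 = expr[case].to_numpy(dtype=float)
    x2 = expr[control].to_numpy(dtype=float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("expression matrix contains missing values")
    n1, n2 = len(case), len(control)
    df_resid = n1 + n2 - 2

    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderated:
        if prior_df is None:
            d0, s0_2 = fit_fdist_moments(s2, df_resid)
        else:
            d0 = float(prior_df)
            _, s0_2 = fit_fdist_moments(s2, df_resid)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        elif d0 == 0:
            s2_tilde = s2
            df_total = df_resid
        else:
            s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        s2_tilde = s2
        df_total = df_resid

    degenerate = s2_tilde == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_tilde) * se_factor)
    t = np.where(degenerate & (lfc == 0), 0.0, t)

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(degenerate & (lfc != 0), 0.0, p)

    entities = expr.index.to_numpy()
    out = pd.DataFrame(
        {
            "entity": entities,
            "role": [entity_role(e) for e in entities],
            "comparison": comparison.name,
            "lfc": lfc,
            "t_stat": t,
            "p_value": p,
            "degenerate": degenerate,
        }
    )
    out["adj_p"] = adjust_bh(out["p_value"].to_numpy())
    return out


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def select_de(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Apply the DE selection rule: |lfc| > threshold and p-column < threshold.

    Both comparisons are strict, matching the conventional wording; the
    p-column is the BH-adjusted p by default (``use_adjusted=False``
    reproduces the raw-p reading).  Adds ``is_de`` and ``direction``
    (up/down for selected entities, empty otherwise).
    """
    if results["comparison"].nunique() > 1:
        raise ValueError("select_de expects results from a single comparison")
    out = results.copy()
    pcol = "adj_p" if use_adjusted else "p_value"
    out["is_de"] = (out["lfc"].abs() > lfc_threshold) & (out[pcol] < p_threshold)
    out["direction"] = np.where(
        out["is_de"], np.where(out["lfc"] > 0, "up", "down"), ""
    )
    return out[RESULT_COLUMNS]


def de_sets(selected: pd.DataFrame) -> dict[str, set[str]]:
    """DE entity ids partitioned by role: keys 'gene', 'TF', 'miRNA', 'all'."""
    de = selected.loc[selected["is_de"]]
    sets = {role: set(g["entity"]) for role, g in de.groupby("role")}
    for role in ("gene", "TF", "miRNA"):
        sets.setdefault(role, set())
    sets["all"] = set(de["entity"])
    return sets
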