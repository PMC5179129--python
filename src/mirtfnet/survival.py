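"""Kaplan-Meier biochemical-recurrence-free survival validation.

Tumor samples are split at the median expression of a candidate marker
(strictly above the median = high group; ties go to the low group, a
convention that makes group sizes reproducible).  Each group gets a
product-limit survival curve and a restricted mean survival time (the
area under the curve up to the largest observed time — the only
well-defined Kaplan-Meier mean under right censoring, reported as MST in
months).  Groups are compared with the standard log-rank test
(chi-square, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time


@dataclass
class KMResult:
    """One group's Kaplan-Meier summary."""

    curve: pd.DataFrame  # columns: time, survival
    n: int
    n_events: int
    mst: float  # restricted mean survival time, months


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("empty survival table")
    if (table["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return table


def median_split(
    expr: pd.DataFrame, entity: str, samples: list[str]
) -> tuple[list[str], list[str]]:
    """Split samples at the entity's median expression.

    High = strictly above the median, low = at or below it.  The split is
    order-invariant; constant expression (no split possible) is an error.
    """
    if entity not in expr.index:
        raise ValueError(f"entity {entity!r} not in expression matrix")
    if len(samples) < 4:
        raise ValueError("need at least 4 samples for a median split")
    values = expr.loc[entity, samples].astype(float)
    if values.nunique() == 1:
        raise ValueError(f"entity {entity!r} has constant expression; no split")
    med = float(values.median())
    high = [s for s in samples if values[s] > med]
    low = [s for s in samples if values[s] <= med]
    return high, low


def km_curve(table: pd.DataFrame) -> KMResult:
    """Product-limit survival curve and restricted mean survival time."""
    table = _check_table(table)
    t = table["time_months"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    mst = float(restricted_mean_survival_time(kmf, t=float(t.max())))
    return KMResult(curve=sf, n=len(t), n_events=int(e.sum()), mst=mst)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Log-rank chi-square (1 df) and p-value comparing two groups."""
    a = _check_table(group_a)
    b = _check_table(group_b)
    if int(a["event"].sum()) + int(b["event"].sum()) == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = logrank_test(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_by_median_expression(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    entity: str,
) -> dict:
    """Full marker validation: median split, per-group KM and log-rank.

    Only samples present in both the expression matrix and the survival
    table enter the analysis.  Returns a dict with the high/low group
    :class:`KMResult` objects and the log-rank statistic and p-value.
    """
    surv = _check_table(survival).set_index("sample")
    samples = [s for s in expr.columns if s in surv.index]
    high, low = median_split(expr, entity, samples)
    tab_high = surv.loc[high].reset_index()
    tab_low = surv.loc[low].reset_index()
    km_high = km_curve(tab_high)
    km_low = km_curve(tab_low)
    chi2, p = logrank(tab_high, tab_low)
    return {
        "entity": entity,
        "high": km_high,
        "low": km_low,
        "logrank_chi2": chi2,
        "logrank_p": p,
    }


def survival_report(
    expr: pd.DataFrame, survival: pd.DataFrame, entities: list[str]
) -> pd.DataFrame:
    """Tidy per-entity table of the median-split survival analysis."""
    rows = []
    for entity in entities:
        r = survival_by_median_expression(expr, survival, entity)
        rows.append(
            (
                entity,
                r["high"].n,
                r["low"].n,
                r["high"].n_events,
                r["low"].n_events,
                r["high"].mst,
                r["low"].mst,
                r["logrank_chi2"],
                r["logrank_p"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "entity",
            "n_high",
            "n_low",
            "events_high",
            "events_low",
            "mst_high",
            "mst_low",
            "chi2",
            "p",
        ],
    )
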