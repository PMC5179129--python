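"""Readers and writers for the pipeline's tab-delimited table dialect.

All tables are UTF-8 TSV with a header row and no quoting: expression
(first column the entity id, remaining columns one per sample), sample
metadata (sample, group), interaction prior (regulator, regulator_type,
target, binding_site_count) and survival (sample, time_months, event).
Readers validate shape, uniqueness and numeric content and raise errors
naming the offending row or column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import GROUPS, PlantedTruth

PRIOR_COLUMNS = ["regulator", "regulator_type", "target", "binding_site_count"]
SURVIVAL_COLUMNS = ["sample", "time_months", "event"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "entity"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate entity ids {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in columns {list(bad)[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample", "group"], path)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"{path}: unknown group labels {sorted(unknown)}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def check_samples_match(expr: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Expression columns and metadata samples must coincide exactly."""
    expr_s = set(expr.columns)
    meta_s = set(meta["sample"])
    if expr_s != meta_s:
        only_e = sorted(expr_s - meta_s)[:5]
        only_m = sorted(meta_s - expr_s)[:5]
        raise ValueError(
            "expression/metadata sample mismatch: "
            f"only in expression {only_e}, only in metadata {only_m}"
        )


def read_prior(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PRIOR_COLUMNS, path)
    bad_type = set(df["regulator_type"]) - {"TF", "miRNA"}
    if bad_type:
        raise ValueError(f"{path}: regulator_type must be TF or miRNA, got {sorted(bad_type)}")
    if not pd.api.types.is_integer_dtype(df["binding_site_count"]):
        raise ValueError(f"{path}: binding_site_count must be integer")
    if (df["binding_site_count"] < 0).any():
        raise ValueError(f"{path}: negative binding_site_count")
    return df[PRIOR_COLUMNS]


def write_prior(prior: pd.DataFrame, path: str | Path) -> None:
    prior.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SURVIVAL_COLUMNS, path)
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if not pd.api.types.is_numeric_dtype(df["time_months"]):
        raise ValueError(f"{path}: non-numeric time_months")
    if (df["time_months"] <= 0).any():
        bad = df.loc[df["time_months"] <= 0, "sample"].tolist()
        raise ValueError(f"{path}: nonpositive times for samples {bad[:5]}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event flags must be 0 or 1")
    return df[SURVIVAL_COLUMNS]


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text(encoding="utf-8"))


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json(), encoding="utf-8")
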