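"""End-to-end orchestration of the regulatory-network analysis.

Stages, in order: (optional) simulation -> differential expression per
stage comparison -> candidate narrowing and correlation filtering ->
integrated network and key-element calling -> binding-site enrichment of
key regulators -> median-split survival validation of key elements.
Every stage writes its table under the output directory and the run ends
with a manifest recording the configuration, versions, seed and the
narrowing counts (prior candidates -> DE-restricted -> correlation-
passing) for each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import correlation, diffexpr, enrichment, io, network, survival
from .diffexpr import DEFAULT_COMPARISONS, Comparison
from .simulate import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    generate_expression,
    generate_priors,
    generate_survival,
)

logger = logging.getLogger("mirtfnet")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for a full run.

    Either the four input table paths or a ``simulate`` block must be
    given.  Threshold defaults are the analysis' standard values: |LFC| >
    1, p < 0.05, |r| > 0.4, z > 2, 10% random sets, 999 resamples.
    """

    expression: str | None = None
    metadata: str | None = None
    prior: str | None = None
    survival: str | None = None
    simulate: SimulationConfig | None = None
    comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted_p: bool = True
    r_threshold: float = 0.4
    tf_p_threshold: float | None = 0.05
    mirna_p_threshold: float | None = None
    tumor_only_correlation: bool = False
    z_threshold: float = 2.0
    key_rule: str = "both"
    random_set_fraction: float = 0.10
    n_resamples: int = 999
    seed: int = 0
    out_dir: str = "mirtfnet_out"

    def __post_init__(self) -> None:
        for name in ("lfc_threshold", "p_threshold", "r_threshold", "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None:
            paths = [self.expression, self.metadata, self.prior, self.survival]
            if any(p is None for p in paths):
                raise ValueError(
                    "either a simulate block or all four input paths are required"
                )
            for p in paths:
                if not Path(p).exists():
                    raise ValueError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = config_from_dict(raw["simulate"])
        if "comparisons" in raw:
            raw["comparisons"] = tuple(
                Comparison(c["name"], c["case_group"], c["control_group"])
                for c in raw["comparisons"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        d["comparisons"] = [dataclasses.asdict(c) for c in self.comparisons]
        return d


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns a dict with the in-memory results: per-comparison DE tables,
    edge tables, networks, key-element reports, enrichment tables, the
    survival report and the manifest.
    """
    out = Path(config.out_dir)
    for sub in ("de", "edges", "networks", "keynodes", "enrichment", "survival"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "counts": {},
    }

    expr, meta, prior, surv = _load_inputs(config, out)
    io.check_samples_match(expr, meta)
    manifest["counts"]["entities"] = int(expr.shape[0])
    manifest["counts"]["samples"] = int(expr.shape[1])
    manifest["counts"]["prior_edges"] = int(len(prior))

    results: dict = {"manifest": manifest, "de": {}, "edges": {}, "networks": {},
                     "keynodes": {}, "enrichment": {}, "survival": None}
    de_sets_by_comp: dict[str, dict[str, set[str]]] = {}

    for comp in config.comparisons:
        de = _run_de(config, expr, meta, comp)
        de.to_csv(out / "de" / f"{comp.name}.tsv", sep="\t", index=False)
        results["de"][comp.name] = de
        de_sets_by_comp[comp.name] = diffexpr.de_sets(de)
        sets = de_sets_by_comp[comp.name]
        manifest["counts"][comp.name] = {
            "de_genes": len(sets["gene"]),
            "de_tfs": len(sets["TF"]),
            "de_mirnas": len(sets["miRNA"]),
        }
        logger.info(
            "%s: %d DEGs, %d DETFs, %d DEMs",
            comp.name, len(sets["gene"]), len(sets["TF"]), len(sets["miRNA"]),
        )

    key_nodes_all: list[str] = []
    for comp in config.comparisons:
        edges, counts = _run_edges(config, expr, meta, prior, de_sets_by_comp, comp)
        edges.to_csv(out / "edges" / f"{comp.name}.tsv", sep="\t", index=False)
        results["edges"][comp.name] = edges
        manifest["counts"][comp.name].update(counts)

        net, report = _run_network(config, edges, results["de"][comp.name], comp)
        network.export_network(net, str(out / "networks" / f"{comp.name}.tsv"), "tsv")
        network.export_network(net, str(out / "networks" / f"{comp.name}.graphml"), "graphml")
        report.to_csv(out / "keynodes" / f"{comp.name}.tsv", sep="\t", index=False)
        results["networks"][comp.name] = net
        results["keynodes"][comp.name] = report
        manifest["counts"][comp.name]["network_nodes"] = net.number_of_nodes()
        manifest["counts"][comp.name]["network_edges"] = net.number_of_edges()
        n_key = int(report["is_key"].sum())
        manifest["counts"][comp.name]["key_elements"] = n_key
        logger.info("%s: network %d nodes / %d edges, %d key elements",
                    comp.name, net.number_of_nodes(), net.number_of_edges(), n_key)
        key_nodes_all.extend(report.loc[report["is_key"], "node"])

        enr = _run_enrichment(config, report, edges, de_sets_by_comp[comp.name], prior)
        enr.to_csv(out / "enrichment" / f"{comp.name}.tsv", sep="\t", index=False)
        results["enrichment"][comp.name] = enr

    surv_report = _run_survival(expr, surv, key_nodes_all)
    surv_report.to_csv(out / "survival" / "key_elements.tsv", sep="\t", index=False)
    results["survival"] = surv_report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return results


def _setup_logging(log_path: Path) -> None:
    if not logger.handlers:
        logger.setLevel(logging.INFO)
        logger.addHandler(logging.StreamHandler())
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    logger.addHandler(logging.FileHandler(log_path, mode="w"))


@_stage("simulate")
def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        sim = config.simulate
        prior = generate_priors(sim)
        expr, meta, truth = generate_expression(sim, prior)
        surv = generate_survival(expr, meta, truth, sim)
        io.write_expression(expr, out / "expression.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_prior(prior, out / "prior.tsv")
        io.write_survival(surv, out / "survival.tsv")
        io.write_truth(truth, out / "truth.json")
        return expr, meta, prior, surv
    return (
        io.read_expression(config.expression),
        io.read_metadata(config.metadata),
        io.read_prior(config.prior),
        io.read_survival(config.survival),
    )


@_stage("diffexpr")
def _run_de(config: PipelineConfig, expr, meta, comp: Comparison) -> pd.DataFrame:
    fitted = diffexpr.fit_two_group(expr, meta, comp, moderated=True)
    return diffexpr.select_de(
        fitted,
        lfc_threshold=config.lfc_threshold,
        p_threshold=config.p_threshold,
        use_adjusted=config.use_adjusted_p,
    )


@_stage("correlation")
def _run_edges(config: PipelineConfig, expr, meta, prior, de_sets_by_comp, comp):
    cands = correlation.candidate_pairs(prior, de_sets_by_comp, comp.name)
    samples = correlation.comparison_sample_universe(
        meta, comp.name, tumor_only=config.tumor_only_correlation
    )
    edges = correlation.filter_pairs(
        cands,
        expr,
        samples,
        r_threshold=config.r_threshold,
        tf_p_threshold=config.tf_p_threshold,
        mirna_p_threshold=config.mirna_p_threshold,
    )
    counts = {"candidate_edges": int(len(cands)), "filtered_edges": int(len(edges))}
    return edges, counts


@_stage("network")
def _run_network(config: PipelineConfig, edges, de, comp: Comparison):
    tf_edges = edges.loc[edges["regulator_type"] == "TF"]
    mir_edges = edges.loc[edges["regulator_type"] == "miRNA"]
    net = network.build_network(tf_edges, mir_edges, de, stage=comp.name)
    report = network.key_elements(net, z_threshold=config.z_threshold, rule=config.key_rule)
    return net, report


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, report, edges, sets, prior) -> pd.DataFrame:
    return enrichment.enrich_key_tfs(
        report,
        edges,
        degs=sets["gene"],
        prior=prior,
        fraction=config.random_set_fraction,
        n_sets=config.n_resamples,
        seed=config.seed,
    )


@_stage("survival")
def _run_survival(expr, surv, key_nodes: list[str]) -> pd.DataFrame:
    entities = sorted(set(key_nodes))
    if not entities:
        return pd.DataFrame(
            columns=["entity", "n_high", "n_low", "events_high", "events_low",
                     "mst_high", "mst_low", "chi2", "p"]
        )
    return survival.survival_report(expr, surv, entities)
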