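"""Synthetic expression / prior / survival data with planted ground truth.

The generator emulates the statistical design of a three-group tumor
profiling study (normal, primary tumor, metastatic tumor) measured on a
log2 expression scale, together with a candidate regulator->target
interaction prior (TRANSFAC / TargetScan-like) and a biochemical-recurrence
survival table.  Every effect the downstream analysis is supposed to find
is planted explicitly and recorded in a :class:`PlantedTruth`, so recovery
rates, false-discovery rates and calibration can be measured exactly.

Planted structure
-----------------
* differential expression: selected entities receive a +/- ``de_effect``
  log2 shift in the case group of a comparison;
* regulons: for each true edge the target's noise term shares a latent
  factor with its regulator, ``target = s*rho*z_reg + sqrt(1-rho^2)*z_own``,
  so the within-group population Pearson correlation is exactly ``s*rho``
  (miRNA loadings are negative by default, a configurable fraction is
  positive to mimic indirect positive miRNA-target correlations);
* hubs: designated regulators receive a large planted out-degree;
* binding sites: counts on true edges are drawn with a higher mean than on
  decoy prior edges;
* survival: exponential event times whose log hazard is proportional to the
  mean centered expression of the planted risk entities, with independent
  right censoring.

All randomness flows from ``config.seed`` through fixed per-artifact
offsets, so regenerating one table never shifts the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("normal", "primary", "metastatic")
#: the two stage comparisons, case vs control
COMPARISONS = ("primary_vs_normal", "metastatic_vs_primary")

ROLE_GENE = "gene"
ROLE_TF = "TF"
ROLE_MIRNA = "miRNA"

# fixed RNG stream offsets per artifact
_OFF_PLAN = 1
_OFF_PRIOR = 2
_OFF_EXPR = 3
_OFF_SURV = 4


def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def tf_ids(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list[str]:
    return [f"miR{i:03d}" for i in range(1, n + 1)]


def entity_role(entity: str) -> str:
    """Role from the id convention: TF### / miR### / anything else = gene."""
    if entity.startswith("TF"):
        return ROLE_TF
    if entity.startswith("miR"):
        return ROLE_MIRNA
    return ROLE_GENE


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-truth generator.

    Defaults are the study conditions the package is exercised under: the
    cohort sizes of the profiled prostate-cancer series (28 normal,
    98 primary, 13 metastatic), a planted |log2 fold change| of 2, regulon
    correlation magnitude 0.8, residual SD 0.5 log2 units, three hub
    regulators, and binding-site means of 5 on true targets vs 1 on
    background.
    """

    n_genes: int = 200
    n_tfs: int = 20
    n_mirnas: int = 30
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 28, "primary": 98, "metastatic": 13}
    )
    de_effect: float = 2.0
    regulon_rho: float = 0.8
    noise_sd: float = 0.5
    prior_density: float = 0.02
    hub_spec: tuple[tuple[str, int], ...] = (
        ("TF001", 12),
        ("TF002", 12),
        ("miR001", 12),
    )
    n_nonhub_true: int = 20
    de_fraction: float = 0.25
    mirna_positive_fraction: float = 0.2
    tf_negative_fraction: float = 0.3
    bs_mean_true: float = 5.0
    bs_mean_bg: float = 1.0
    hazard_coef: float = 1.0
    censor_rate: float = 0.3
    baseline_hazard: float = math.log(2) / 60.0  # per month; median ~60 months
    risk_entities: tuple[str, ...] | None = None  # None -> hub regulators
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tfs, self.n_mirnas) <= 0:
            raise ValueError("entity counts must be positive")
        for g in GROUPS:
            if g not in self.group_sizes:
                raise ValueError(f"group_sizes missing group {g!r}")
            if self.group_sizes[g] < 2:
                raise ValueError(
                    f"group {g!r} has size {self.group_sizes[g]}; "
                    "need >= 2 samples per group for variance estimation"
                )
        if not 0.0 <= self.regulon_rho < 1.0:
            raise ValueError("regulon_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.prior_density <= 1.0:
            raise ValueError("prior_density must be in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        regs = set(tf_ids(self.n_tfs)) | set(mirna_ids(self.n_mirnas))
        for hub, k in self.hub_spec:
            if hub not in regs:
                raise ValueError(f"hub {hub!r} is not a TF or miRNA id")
            if k <= 0:
                raise ValueError(f"hub {hub!r} out-degree must be positive")

    @property
    def regulators(self) -> list[str]:
        return tf_ids(self.n_tfs) + mirna_ids(self.n_mirnas)

    @property
    def entities(self) -> list[str]:
        return gene_ids(self.n_genes) + self.regulators


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset.

    ``de_entities`` holds (entity, comparison, sign) triples, ``true_edges``
    holds (regulator, target, sign) triples, ``hub_nodes`` the planted
    super-connected regulators and ``risk_entities`` the entities whose
    expression drives the survival hazard.
    """

    de_entities: set[tuple[str, str, int]]
    true_edges: set[tuple[str, str, int]]
    hub_nodes: set[str]
    risk_entities: set[str]

    def de_set(self, comparison: str) -> set[str]:
        return {e for e, c, _ in self.de_entities if c == comparison}

    def edges_of(self, regulator: str) -> set[str]:
        return {t for r, t, _ in self.true_edges if r == regulator}

    def to_json(self) -> str:
        payload = {
            "de_entities": sorted(self.de_entities),
            "true_edges": sorted(self.true_edges),
            "hub_nodes": sorted(self.hub_nodes),
            "risk_entities": sorted(self.risk_entities),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            de_entities={(e, c, int(s)) for e, c, s in d["de_entities"]},
            true_edges={(r, t, int(s)) for r, t, s in d["true_edges"]},
            hub_nodes=set(d["hub_nodes"]),
            risk_entities=set(d["risk_entities"]),
        )


@dataclass(frozen=True)
class _Plan:
    """Deterministic planted layout shared by prior and expression draws."""

    edges: tuple[tuple[str, str, int], ...]  # (regulator, target, sign)
    de_signs: Mapping[tuple[str, str], int]  # (entity, comparison) -> sign


def _plan_truth(config: SimulationConfig) -> _Plan:
    """Lay out true edges, their signs and the planted DE assignment.

    Re-derived (identically, from seed + fixed offset) by both
    :func:`generate_priors` and :func:`generate_expression`.
    """
    rng = np.random.default_rng(config.seed + _OFF_PLAN)
    genes = gene_ids(config.n_genes)

    # each gene serves as the target of at most one true edge so the
    # planted population PCC of every pair is exactly +/- rho
    free_targets = list(genes)
    edges: list[tuple[str, str, int]] = []

    hub_names = [h for h, _ in config.hub_spec]
    for hub, k in config.hub_spec:
        if k > len(free_targets):
            raise ValueError(
                f"hub {hub!r} requests out-degree {k} but only "
                f"{len(free_targets)} unassigned targets remain"
            )
        chosen = rng.choice(len(free_targets), size=k, replace=False)
        for i in sorted(chosen, reverse=True):
            target = free_targets.pop(i)
            edges.append((hub, target, _edge_sign(hub, rng, config)))

    nonhub_regs = [r for r in config.regulators if r not in hub_names]
    n_extra = min(config.n_nonhub_true, len(free_targets), len(nonhub_regs))
    if n_extra > 0:
        regs = rng.choice(len(nonhub_regs), size=n_extra, replace=False)
        tgts = rng.choice(len(free_targets), size=n_extra, replace=False)
        for ri, ti in zip(regs, tgts):
            reg = nonhub_regs[ri]
            edges.append((reg, free_targets[ti], _edge_sign(reg, rng, config)))

    # DE planting: every true-edge endpoint is differentially expressed in
    # both stage comparisons; the target's DE sign equals the regulator's
    # times the edge sign, so mean structure and latent factor agree
    de_signs: dict[tuple[str, str], int] = {}
    reg_sign: dict[str, int] = {}
    for comparison in COMPARISONS:
        for reg, target, s in edges:
            if (reg, comparison) not in de_signs:
                reg_sign[reg] = int(rng.choice([-1, 1]))
                de_signs[(reg, comparison)] = reg_sign[reg]
            de_signs[(target, comparison)] = de_signs[(reg, comparison)] * s

    # decoy DE entities (no planted regulation) at de_fraction
    involved = {e for e, _ in de_signs}
    for comparison in COMPARISONS:
        for entity in config.entities:
            if entity in involved:
                continue
            if rng.random() < config.de_fraction:
                de_signs[(entity, comparison)] = int(rng.choice([-1, 1]))

    return _Plan(edges=tuple(edges), de_signs=de_signs)


def _edge_sign(regulator: str, rng: np.random.Generator, config: SimulationConfig) -> int:
    if entity_role(regulator) == ROLE_MIRNA:
        return 1 if rng.random() < config.mirna_positive_fraction else -1
    return -1 if rng.random() < config.tf_negative_fraction else 1


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """The ground truth implied by ``config`` (no data generated)."""
    plan = _plan_truth(config)
    true_edges = set(plan.edges) if config.regulon_rho > 0 else set()
    de_entities = (
        {(e, c, s) for (e, c), s in plan.de_signs.items()}
        if config.de_effect != 0
        else set()
    )
    hub_nodes = {h for h, _ in config.hub_spec} if true_edges else set()
    if config.risk_entities is not None:
        risk = set(config.risk_entities)
    else:
        risk = {h for h, _ in config.hub_spec}
    return PlantedTruth(
        de_entities=de_entities,
        true_edges=true_edges,
        hub_nodes=hub_nodes,
        risk_entities=risk,
    )


def generate_priors(config: SimulationConfig) -> pd.DataFrame:
    """Candidate regulator->target prior table with binding-site counts.

    Columns: regulator, regulator_type, target, binding_site_count.  True
    (planted) edges are always present; decoy edges are sampled at
    ``prior_density`` over the remaining regulator x gene pairs.
    Binding-site counts are 1 + Poisson(mean - 1), i.e. positive integers
    with the configured mean, larger on true edges.
    """
    plan = _plan_truth(config)
    rng = np.random.default_rng(config.seed + _OFF_PRIOR)
    genes = gene_ids(config.n_genes)

    true_pairs = {(r, t) for r, t, _ in plan.edges}
    rows: list[tuple[str, str, str, int]] = []
    for reg, target, _sign in plan.edges:
        rows.append((reg, entity_role(reg), target, _bs_count(rng, config.bs_mean_true)))
    if config.prior_density > 0:
        for reg in config.regulators:
            mask = rng.random(len(genes)) < config.prior_density
            for gi in np.flatnonzero(mask):
                target = genes[gi]
                if (reg, target) in true_pairs:
                    continue
                rows.append(
                    (reg, entity_role(reg), target, _bs_count(rng, config.bs_mean_bg))
                )

    prior = pd.DataFrame(
        rows, columns=["regulator", "regulator_type", "target", "binding_site_count"]
    )
    return prior.sort_values(["regulator", "target"], kind="stable").reset_index(drop=True)


def _bs_count(rng: np.random.Generator, mean: float) -> int:
    return int(1 + rng.poisson(max(mean - 1.0, 0.0)))


def sample_ids(config: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    prefixes = {"normal": "N", "primary": "P", "metastatic": "M"}
    samples: list[str] = []
    groups: list[str] = []
    for g in GROUPS:
        for i in range(1, config.group_sizes[g] + 1):
            samples.append(f"{prefixes[g]}{i:03d}")
            groups.append(g)
    meta = pd.DataFrame({"sample": samples, "group": groups})
    return samples, meta


def generate_expression(
    config: SimulationConfig, prior: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the log2 expression matrix (entities x samples).

    Returns ``(expression, sample_metadata, truth)``.  Each value is
    baseline + planted group effect + noise_sd * z, where the z of a true
    target shares a latent factor with its regulator's z (loading
    sign*rho), making the within-group population correlation exactly
    sign*rho.  Group effects: a +/-de_effect shift in primary AND
    metastatic samples for entities planted in the primary-vs-normal
    comparison (progression retains primary-stage changes), and an
    additional shift in metastatic samples for the metastatic-vs-primary
    comparison.
    """
    plan = _plan_truth(config)
    truth = planted_truth(config)
    rng = np.random.default_rng(config.seed + _OFF_EXPR)

    entities = config.entities
    samples, meta = sample_ids(config)
    n_ent, n_samp = len(entities), len(samples)
    ent_idx = {e: i for i, e in enumerate(entities)}

    baseline = rng.normal(8.0, 1.0, size=n_ent)
    z = rng.standard_normal((n_ent, n_samp))

    # regulon latent factors (only when a correlation is actually planted)
    if config.regulon_rho > 0:
        rho = config.regulon_rho
        for reg, target, sign in plan.edges:
            zr = z[ent_idx[reg]]
            zt = z[ent_idx[target]]
            z[ent_idx[target]] = sign * rho * zr + np.sqrt(1 - rho**2) * zt

    values = baseline[:, None] + config.noise_sd * z

    if config.de_effect != 0:
        grp = meta["group"].to_numpy()
        in_primary = grp == "primary"
        in_metastatic = grp == "metastatic"
        for (entity, comparison), sign in plan.de_signs.items():
            shift = sign * config.de_effect
            row = ent_idx[entity]
            if comparison == "primary_vs_normal":
                values[row, in_primary | in_metastatic] += shift
            else:
                values[row, in_metastatic] += shift

    expr = pd.DataFrame(values, index=pd.Index(entities, name="entity"), columns=samples)
    return expr, meta, truth


def generate_survival(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate BCR-free survival for tumor samples.

    Event times are exponential with log hazard
    ``log(baseline_hazard) + hazard_coef * xbar`` where ``xbar`` is the mean
    centered expression of the risk entities; censoring is independent with
    probability ``censor_rate``, reporting a uniform time before the event.
    Columns: sample, time_months, event (1 = BCR, 0 = censored).
    """
    if config.hazard_coef != 0 and not truth.risk_entities:
        raise ValueError("hazard_coef is nonzero but the risk-entity set is empty")
    missing = truth.risk_entities - set(expr.index)
    if missing:
        raise ValueError(f"risk entities absent from expression matrix: {sorted(missing)}")

    rng = np.random.default_rng(config.seed + _OFF_SURV)
    tumor = meta.loc[meta["group"].isin(["primary", "metastatic"]), "sample"].tolist()

    if config.hazard_coef != 0:
        sub = expr.loc[sorted(truth.risk_entities), tumor]
        centered = sub.sub(sub.mean(axis=1), axis=0)
        xbar = centered.mean(axis=0).to_numpy()
    else:
        xbar = np.zeros(len(tumor))

    rate = config.baseline_hazard * np.exp(config.hazard_coef * xbar)
    times = rng.exponential(1.0 / rate)
    censored = rng.random(len(tumor)) < config.censor_rate
    observed = np.where(censored, rng.uniform(0, times), times)
    observed = np.maximum(observed, 1e-6)  # times strictly positive

    return pd.DataFrame(
        {
            "sample": tumor,
            "time_months": observed,
            "event": (~censored).astype(int),
        }
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["group_sizes"] = dict(d["group_sizes"])
    d["hub_spec"] = [list(h) for h in d["hub_spec"]]
    if d["risk_entities"] is not None:
        d["risk_entities"] = list(d["risk_entities"])
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "hub_spec" in d:
        d["hub_spec"] = tuple((str(h), int(k)) for h, k in d["hub_spec"])
    if d.get("risk_entities") is not None:
        d["risk_entities"] = tuple(d["risk_entities"])
    return SimulationConfig(**d)
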