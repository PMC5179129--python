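"""Generator contracts: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from mirtfnet.diffexpr import Comparison, fit_two_group, select_de
from mirtfnet.simulate import (
    PlantedTruth,
    SimulationConfig,
    generate_expression,
    generate_priors,
    generate_survival,
    planted_truth,
)
from mirtfnet.survival import km_curve

from conftest import null_config


class TestConfigValidation:
    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            SimulationConfig(group_sizes={"normal": 1, "primary": 5, "metastatic": 5})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"regulon_rho": 1.0},
            {"noise_sd": 0.0},
            {"censor_rate": 1.0},
            {"hub_spec": (("G0001", 5),)},
            {"n_genes": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestPriors:
    def test_zero_density_no_hubs_gives_empty_table(self):
        cfg = null_config(seed=0, prior_density=0.0)
        assert generate_priors(cfg).empty

    def test_hub_appears_with_exactly_requested_out_degree(self):
        cfg = SimulationConfig(
            seed=3, hub_spec=(("TF001", 15),), prior_density=0.0, n_nonhub_true=0
        )
        prior = generate_priors(cfg)
        assert (prior["regulator"] == "TF001").sum() == 15
        assert len(prior) == 15

    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = SimulationConfig(seed=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_priors(cfg).to_csv(p1, sep="\t", index=False)
        generate_priors(cfg).to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_hub_out_degree_exceeding_targets_errors_naming_hub(self):
        cfg = SimulationConfig(n_genes=10, hub_spec=(("TF001", 11),))
        with pytest.raises(ValueError, match="TF001"):
            generate_priors(cfg)

    def test_binding_site_counts_positive_and_higher_on_true_edges(self):
        cfg = SimulationConfig(seed=8)
        prior = generate_priors(cfg)
        truth = planted_truth(cfg)
        assert (prior["binding_site_count"] >= 1).all()
        true_pairs = {(r, t) for r, t, _ in truth.true_edges}
        is_true = [
            (r, t) in true_pairs
            for r, t in zip(prior["regulator"], prior["target"])
        ]
        counts = prior["binding_site_count"].to_numpy()
        assert counts[np.array(is_true)].mean() > counts[~np.array(is_true)].mean() + 2


class TestExpression:
    def test_same_seed_identical_matrices(self):
        cfg = SimulationConfig(seed=2)
        e1, m1, _ = generate_expression(cfg)
        e2, m2, _ = generate_expression(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_planted_effect_realized_within_clt_bound(self):
        """Planted +2 log2 shift appears in the group means to CLT accuracy."""
        cfg = SimulationConfig(seed=4)
        expr, meta, truth = generate_expression(cfg)
        primary = meta.loc[meta["group"] == "primary", "sample"]
        normal = meta.loc[meta["group"] == "normal", "sample"]
        n_eff = 1 / (1 / len(primary) + 1 / len(normal))
        bound = 3 * cfg.noise_sd / np.sqrt(n_eff)
        checked = 0
        for entity, comparison, sign in truth.de_entities:
            if comparison != "primary_vs_normal":
                continue
            diff = expr.loc[entity, primary].mean() - expr.loc[entity, normal].mean()
            assert abs(diff - sign * cfg.de_effect) < bound
            checked += 1
        assert checked > 20

    def test_true_pair_correlation_exceeds_threshold_at_high_rho(self):
        """rho=0.9, low noise, 60 samples: every true pair has |r| > 0.4.

        Fisher-z at rho 0.9 puts r = 0.4 about eight standard errors below
        the mean, so failures over a handful of seeds are essentially
        impossible.
        """
        for seed in range(30, 40):
            cfg = SimulationConfig(
                seed=seed,
                regulon_rho=0.9,
                noise_sd=0.1,
                de_effect=0.0,
                group_sizes={"normal": 30, "primary": 28, "metastatic": 2},
            )
            expr, meta, _ = generate_expression(cfg)
            plan_truth = planted_truth(cfg)
            samples = meta.loc[meta["group"].isin(["normal", "primary"]), "sample"]
            sub = expr[samples]
            for reg, target, sign in plan_truth.true_edges:
                r = np.corrcoef(sub.loc[reg], sub.loc[target])[0, 1]
                assert abs(r) > 0.4
                assert np.sign(r) == sign

    def test_null_config_de_rate_at_most_nominal(self):
        """With no planted effects the BH-flagged fraction stays <= 0.05."""
        comp = Comparison("primary_vs_normal", "primary", "normal")
        flagged, total = 0, 0
        for seed in range(50, 60):
            cfg = null_config(seed)
            expr, meta, _ = generate_expression(cfg)
            res = select_de(fit_two_group(expr, meta, comp))
            flagged += int(res["is_de"].sum())
            total += len(res)
        se = np.sqrt(0.05 * 0.95 / total)
        assert flagged / total <= 0.05 + 3 * se


class TestTruth:
    def test_truth_completeness_and_invariants(self, planted_dataset):
        truth: PlantedTruth = planted_dataset["truth"]
        expr = planted_dataset["expr"]
        regulators = {r for r, _, _ in truth.true_edges}
        assert truth.hub_nodes <= regulators
        for reg, target, sign in truth.true_edges:
            assert reg in expr.index and target in expr.index
            assert sign in (-1, 1)
        cfg = planted_dataset["config"]
        for hub, k in cfg.hub_spec:
            assert len(truth.edges_of(hub)) == k

    def test_truth_json_round_trip(self, planted_dataset):
        truth = planted_dataset["truth"]
        again = PlantedTruth.from_json(truth.to_json())
        assert again == truth

    def test_null_config_truth_is_empty(self):
        truth = planted_truth(null_config(1))
        assert not truth.de_entities and not truth.true_edges and not truth.hub_nodes


class TestSurvival:
    def test_zero_censoring_gives_all_events(self, planted_dataset):
        cfg = SimulationConfig(seed=11, censor_rate=0.0)
        expr, meta, truth = generate_expression(cfg)
        surv = generate_survival(expr, meta, truth, cfg)
        assert (surv["event"] == 1).all()

    def test_empty_risk_set_with_nonzero_hazard_errors(self):
        cfg = null_config(7, hazard_coef=1.0)
        expr, meta, truth = generate_expression(cfg)
        with pytest.raises(ValueError, match="risk"):
            generate_survival(expr, meta, truth, cfg)

    def test_only_tumor_samples_and_positive_times(self, planted_dataset):
        surv = planted_dataset["survival"]
        meta = planted_dataset["meta"]
        tumor = set(meta.loc[meta["group"] != "normal", "sample"])
        assert set(surv["sample"]) == tumor
        assert (surv["time_months"] > 0).all()

    def test_high_expression_of_risk_entity_shortens_survival(self):
        """Marker-split direction: the hazard driver's high group has the
        smaller restricted mean survival time in (almost) every seed."""
        worse, n_seeds = 0, 15
        for seed in range(70, 70 + n_seeds):
            cfg = SimulationConfig(seed=seed, risk_entities=("TF001",))
            expr, meta, truth = generate_expression(cfg)
            surv = generate_survival(expr, meta, truth, cfg)
            vals = expr.loc["TF001", surv["sample"]]
            med = vals.median()
            hi = surv[vals.to_numpy() > med]
            lo = surv[vals.to_numpy() <= med]
            worse += km_curve(hi).mst < km_curve(lo).mst
        assert worse >= n_seeds - 1
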