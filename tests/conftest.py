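import pytest

from mirtfnet.simulate import (
    SimulationConfig,
    generate_expression,
    generate_priors,
    generate_survival,
)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """No planted effects: pure-noise expression, decoy-only prior."""
    base = dict(
        de_effect=0.0,
        regulon_rho=0.0,
        hub_spec=(),
        n_nonhub_true=0,
        prior_density=0.05,
        hazard_coef=0.0,
        group_sizes={"normal": 30, "primary": 30, "metastatic": 13},
    )
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def planted_dataset():
    """One full synthetic dataset under the default planted-truth design."""
    cfg = SimulationConfig(seed=11)
    prior = generate_priors(cfg)
    expr, meta, truth = generate_expression(cfg, prior)
    surv = generate_survival(expr, meta, truth, cfg)
    return {
        "config": cfg,
        "prior": prior,
        "expr": expr,
        "meta": meta,
        "truth": truth,
        "survival": surv,
    }
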