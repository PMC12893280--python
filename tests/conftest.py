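import numpy as np
import pytest

from popthreat.model import ModelSpec, ThreatTrendModel
from popthreat.simulate import (
    DEFAULT_TREND_EFFECTS,
    GeneratorConfig,
    generate,
    interaction_scenario_config,
)
from popthreat.threat_design import YEAR_SUFFIX


@pytest.fixture(scope="session")
def recovery_setup():
    """Known-truth recovery study: 120 series of 25 points, sigma_obs = 0.3,
    rho = 0.3, one interaction trend effect of -0.08; desk-scale fit."""
    beta = dict(DEFAULT_TREND_EFFECTS)
    beta["exploitation.habitat_loss" + YEAR_SUFFIX] = -0.08
    cfg = GeneratorConfig(
        n_species=24,
        populations_per_species=5,
        n_sites=40,
        span_range=(25, 25),
        missing_rate=0.0,
        true_beta=beta,
        seed=11,
    )
    series, truth = generate(cfg)
    model = ThreatTrendModel(series)
    results = model.fit(ModelSpec.desk(seed=5))
    return model, results, truth


@pytest.fixture(scope="session")
def small_fit():
    """Quick fit on a designed scenario (disease/exploitation singles and
    their pair, negative interaction truth, invasive absent from the data)."""
    cfg = interaction_scenario_config(
        n_pair=10,
        n_single_each=10,
        n_none=10,
        interaction_effect=-0.05,
        span_range=(15, 15),
        missing_rate=0.0,
        n_sites=12,
        seed=21,
    )
    series, truth = generate(cfg)
    model = ThreatTrendModel(series)
    results = model.fit(chains=2, iterations=500, warmup=250, seed=3)
    return model, results, truth


@pytest.fixture
def toy_series():
    from popthreat.data_io import PopulationSeries

    def mk(pid, years, abund, threats=(), lat=10.0, lon=20.0, sp="SP1"):
        return PopulationSeries(
            population_id=pid,
            species_id=sp,
            site=(lat, lon),
            system="terrestrial",
            taxon="bird",
            observations=tuple(zip(years, abund)),
            threats=frozenset(threats),
        )

    return mk
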