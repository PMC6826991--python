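"""Shared fixtures: one small simulated experiment reused across test modules.

The small world: one drug (gemcitabine dose series), 64 reference replicate
cultures, 40 mutants of which 3 are planted L-enhancers, 3 L-suppressors and
2 shift-only strains; default intensity noise. Session-scoped because the
fit step dominates test runtime.
"""

from __future__ import annotations

import pytest

from phenomiq import SimulationConfig, StrainEffects, generate_plate_experiment
from phenomiq.growth import fit_cpp_table
from phenomiq.interaction import score_all

GEM = "gemcitabine"
GEM_DOSES = (0.0, 5.0, 10.0, 20.0, 30.0)

ENHANCERS = ("YKO_0001", "YKO_0002", "YKO_0003")
SUPPRESSORS = ("YKO_0004", "YKO_0005", "YKO_0006")
SHIFT_ONLY = ("YKO_0007", "YKO_0008")


def small_config(**overrides) -> SimulationConfig:
    effects = {}
    for s in ENHANCERS:
        effects[s] = StrainEffects(slopes={GEM: {"L": 0.30, "K": -3.0}})
    for s in SUPPRESSORS:
        effects[s] = StrainEffects(slopes={GEM: {"L": -0.30, "K": 3.0}})
    for s in SHIFT_ONLY:
        effects[s] = StrainEffects(shift={"K": 25.0, "L": 4.0})
    base = dict(
        seed=7,
        n_mutant_strains=40,
        n_reference_cultures=64,
        doses_by_drug={GEM: GEM_DOSES},
        planted_effects=effects,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def experiment():
    config = small_config()
    timeseries, truth = generate_plate_experiment(config)
    return config, timeseries, truth


@pytest.fixture(scope="session")
def cpp_table(experiment):
    _, timeseries, _ = experiment
    return fit_cpp_table(timeseries)


@pytest.fixture(scope="session")
def scored(cpp_table):
    return score_all(cpp_table, GEM)
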