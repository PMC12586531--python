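"""Shared fixtures: the packaged registry and a small reference run.

The small run is session-scoped and reused by conservation, direction-of-
effect and outcome tests; it keeps per-simulant probabilities and person-year
flags so invariants can be checked at the individual level.
"""

import numpy as np
import pytest

from morbsim import Microsimulation, RunConfig, Scenario, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_results():
    """1,500 simulants, 2 iterations, base case + TMREL-all + 10% improvement."""
    cfg = RunConfig(
        n_simulants=1_500,
        n_iterations=2,
        master_seed=20240117,
        scenarios=[
            Scenario.baseline(),
            Scenario(name="tmrel_all", family="tmrel"),
            Scenario(name="improve10_all", family="relative_improvement"),
        ],
        keep_probabilities=True,
        keep_person_years=True,
    )
    return Microsimulation(cfg).run()


@pytest.fixture(scope="session")
def small_cohort(registry):
    from morbsim import default_generator_config, generate_population

    cfg = default_generator_config(registry, n_simulants=800, end_year=2030)
    cohort, targets, exposures = generate_population(cfg, 7, registry)
    return cfg, cohort, targets, exposures


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
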