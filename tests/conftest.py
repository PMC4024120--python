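import logging

import pytest

from lsdpanel.pipeline import run_pipeline
from lsdpanel.simulate import SimulationConfig, simulate_cohort

logging.disable(logging.WARNING)  # triage emits per-variant zygosity warnings


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study (30 samples, 10 genes), seed 1."""
    return simulate_cohort(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    return run_pipeline(
        cohort.panel,
        {
            cohort.config.caller_a: cohort.calls_a,
            cohort.config.caller_b: cohort.calls_b,
        },
        profiles=cohort.coverage.profiles,
        truth=cohort.manifest.truth_set(),
        predictions=cohort.manifest.predictions,
    )
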