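import numpy as np
import pytest

from chiralspec import design, pipeline, simulate


@pytest.fixture(scope="session")
def design_df():
    return design.load_design()


@pytest.fixture(scope="session")
def study_report():
    """One full default study run (seed 0), shared across tests."""
    return pipeline.run_study(pipeline.RunConfig(seed=0))


def clean_profile(replicates: int = 1, seed: int = 0, **overrides) -> simulate.InstrumentProfile:
    """An artifact-free instrument profile (every sd zero)."""
    kwargs = dict(
        scatter_sd=0.0,
        offset_sd=0.0,
        baseline_sd=0.0,
        humidity_sd=0.0,
        noise_sd=0.0,
        replicates=replicates,
        seed=seed,
    )
    kwargs.update(overrides)
    return simulate.InstrumentProfile(**kwargs)


@pytest.fixture
def rng():
    """Fresh, fixed-seed generator per test (keeps tests order-independent)."""
    return np.random.default_rng(20210815)
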