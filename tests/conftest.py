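import pytest
from hypothesis import HealthCheck, settings

from rvburden.simulate import (
    SyntheticConfig,
    generate_cohort,
    generate_worked_example,
    write_bundle,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_bundle():
    """Deterministic fixture reproducing the published group means."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def cohort_bundle():
    """Sampled cohort with an enriched gene set, a PRS frequency shift, and
    decoy (low-quality / common) variants exercising the discard path."""
    cfg = SyntheticConfig(
        seed=11,
        geneset_effect={"NEURON_PROJECTION": 2.0},
        prs_freq_shift=0.15,
        low_quality_rate=1.0,
        common_rate=2.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """Cohort generated with no group differences anywhere."""
    return generate_cohort(SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def cohort_files(cohort_bundle, tmp_path_factory):
    """The sampled cohort written out as the on-disk input formats."""
    out = tmp_path_factory.mktemp("cohort")
    return write_bundle(cohort_bundle, out)
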