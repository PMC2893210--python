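import pytest

from aai_score import CohortSpec, GroupSpec, reference_scenario


@pytest.fixture(scope="session")
def scenario() -> CohortSpec:
    """The default four-group strain/knockout scenario."""
    return reference_scenario()


@pytest.fixture
def tiny_spec() -> CohortSpec:
    """A minimal noiseless two-group cohort for exact-value tests."""
    return CohortSpec(
        groups=(
            GroupSpec(name="responder", slopes={"IL-4": 0.1, "IL-13": 0.05}),
            GroupSpec(name="nonresponder", slopes={"IL-4": 0.0, "IL-13": 0.0}),
        ),
        analytes=("IL-4", "IL-13"),
        n_per_dose=2,
        sigma=0.0,
    )
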