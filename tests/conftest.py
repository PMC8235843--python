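import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_example():
    """Four-gene illustration: means 5 and 6, change +1."""
    from ctdna_kinetics import worked_example_patient

    return worked_example_patient()


@pytest.fixture(scope="session")
def fixture_cohort():
    from ctdna_kinetics import make_paper_fixture

    return make_paper_fixture()


def make_call(**overrides):
    from ctdna_kinetics import VariantCall

    base = dict(
        patient_id="P1",
        timepoint="baseline",
        gene="TP53",
        variant_class="SNV",
        hgvs_p="R175H",
        vaf=1.0,
    )
    base.update(overrides)
    return VariantCall(**base)


@pytest.fixture
def call_factory():
    return make_call
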