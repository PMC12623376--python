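import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def questionnaire():
    from varpheno import default_questionnaire

    return default_questionnaire()


@pytest.fixture(scope="session")
def example_kb():
    from varpheno import example_knowledgebase

    return example_knowledgebase()


@pytest.fixture(scope="session")
def panel():
    from varpheno import default_panel

    return default_panel()


#: The ten core screening indicators of the worked example.
CORE_INDICATORS = [
    "muscle weakness",
    "frequent falls",
    "breathing difficulties",
    "cardiac involvement",
    "difficulty in swallowing",
    "difficulty in climbing stairs",
    "toe walking",
    "joint contractures",
    "cognitive impairment",
    "impaired vision",
]

#: The eight symptoms of the worked dystroglycanopathy prioritization.
DYSTRO_SYMPTOMS = [
    "ophthalmoplegia",
    "facial muscle weakness",
    "hypotonia",
    "white matter signal abnormalities",
    "dysmorphism",
    "growth failure",
    "spasticity",
    "spastic paralysis of legs",
]


@pytest.fixture(scope="session")
def core_indicators():
    return list(CORE_INDICATORS)


@pytest.fixture(scope="session")
def dystro_symptoms():
    return list(DYSTRO_SYMPTOMS)
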