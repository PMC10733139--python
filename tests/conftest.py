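import pytest

from tra_consumer import (
    ADULT,
    CHILD,
    ExposureScenario,
    Substance,
    default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def flooring(registry):
    """Plastic-flooring article scenario (WF 0.1, TL 0.01 cm, SA 8750 cm2)."""
    return registry.get("AC13-plastic-flooring")


@pytest.fixture
def volatile_substance():
    """Water-like volatile: MW 18 g/mol, VP 2337 Pa."""
    return Substance(name="volatile", molecular_weight=18.0, vapor_pressure=2337.0)


@pytest.fixture
def svoc_substance():
    """Plasticizer-like semi-volatile with article-side properties."""
    return Substance(
        name="svoc",
        molecular_weight=390.0,
        vapor_pressure=3.4e-5,
        density=0.99,
        diffusion_coefficient=1e-10,
        article_concentration=0.1,
    )


@pytest.fixture
def adult():
    return ADULT


@pytest.fixture
def child():
    return CHILD


@pytest.fixture
def basic_product():
    """One-substance liquid product scenario exercising all three routes."""
    return ExposureScenario(
        category_code="PC-test",
        product_amount=20.0,
        weight_fraction=1.0,
        room_volume=20.0,
        event_duration=2.0,
        skin_contact_area=428.0,
        thickness_layer=0.01,
        ingested_amount=0.001,
    )
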