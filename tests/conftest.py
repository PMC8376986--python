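import pytest

from emofacs import default_registry, worked_fixture
from emofacs.core import ConfigurationRegistry, ConfigurationVariant


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_bundle():
    """The 12-scenario noiseless worked bundle."""
    return worked_fixture()


@pytest.fixture(scope="session")
def fear_registry():
    """Minimal registry whose fear variants are 1+2+5 with/without 25/26/27.

    Other categories get placeholder single variants so registry
    invariants hold.
    """
    from emofacs.core import CATEGORIES

    fear_variants = [
        frozenset({1, 2, 5}),
        frozenset({1, 2, 5, 25}),
        frozenset({1, 2, 5, 26}),
        frozenset({1, 2, 5, 27}),
    ]
    variants = {}
    for i, cat in enumerate(CATEGORIES):
        if cat == "fear":
            variants[cat] = [ConfigurationVariant(cat, v) for v in fear_variants]
        else:
            variants[cat] = [
                ConfigurationVariant(cat, frozenset({6 + (i % 3), 12 + i}))
            ]
    return ConfigurationRegistry(variants=variants)
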