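import pytest
from hypothesis import settings

import dblipid as dl

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return dl.default_registry()


@pytest.fixture(scope="session")
def lead(registry):
    """The lead DB-lipidoid 11-10-8 (amine 11 + C10 body + C8 branch)."""
    return dl.synthesize(
        registry.get("amine-11"), registry.get("epoxide-10"), registry.get("acyl-8")
    )


@pytest.fixture(scope="session")
def library1(registry):
    return dl.enumerate_library(registry, dl.library_1_design(registry))


@pytest.fixture(scope="session")
def both_libraries_verdicts(registry):
    """Verdict table + summary over Libraries 1 and 2, deduplicated."""
    return dl.screen_library(
        registry,
        [dl.library_1_design(registry), dl.library_2_design(registry)],
    )


@pytest.fixture(scope="session")
def factorial_verdicts(registry):
    """Verdict table over the full 20 x 5 x 5 factorial."""
    design = dl.LibraryDesign.of(
        [b.id for b in registry.amines],
        [b.id for b in registry.epoxides],
        [b.id for b in registry.acyl_chlorides],
    )
    table, summary = dl.screen_library(registry, design)
    return table, summary


@pytest.fixture(scope="session")
def factorial_descriptors(registry):
    design = dl.LibraryDesign.of(
        [b.id for b in registry.amines],
        [b.id for b in registry.epoxides],
        [b.id for b in registry.acyl_chlorides],
    )
    lipidoids = dl.enumerate_library(registry, design)
    return dl.describe_library(lipidoids, registry)
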