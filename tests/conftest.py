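import pytest

import cvdburden as cb


@pytest.fixture(scope="session")
def reference_projection():
    """The packaged published 2005/2025 DALY projection table."""
    return cb.load_reference_projection()


@pytest.fixture(scope="session")
def base_pyramid():
    """The default 2005-like synthetic pyramid (70.1M, young-adult bulge)."""
    return cb.make_base_population(
        total_size=70_122_200,
        bulge_age=22,
        spread=18,
        sex_gap_30plus=889_000,
        seed=1,
    )


@pytest.fixture(scope="session")
def mortality():
    return cb.make_mortality_schedule(adult_level=1.0, seed=1)


@pytest.fixture(scope="session")
def fertility():
    return cb.make_fertility_schedule(tfr_target=1.77)
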