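import pytest

import woundage as wa
from woundage.panel import load_panel
from woundage.screen import PanelSet


@pytest.fixture(scope="session")
def scheme():
    return wa.default_scheme()


@pytest.fixture(scope="session")
def default_config():
    return wa.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_config):
    return wa.generate_study(default_config)


@pytest.fixture(scope="session")
def small_config():
    # fewer background features: faster screens, same statistical structure
    return wa.SyntheticConfig(seed=2, n_background=60)


@pytest.fixture(scope="session")
def small_study(small_config):
    return wa.generate_study(small_config)


@pytest.fixture(scope="session")
def full_panelset(scheme):
    """All 43 panel metabolites at every node; bypasses screening."""
    names = tuple(rec.name for rec in load_panel())
    return PanelSet(
        union=names,
        per_node={group: names for group in scheme.fine},
        per_group_counts={group: len(names) for group in scheme.fine},
    )


@pytest.fixture(scope="session")
def fitted_tandem(small_study, scheme):
    return wa.build_tandem(small_study, scheme, seed=2)
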