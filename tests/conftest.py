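import numpy as np
import pytest

from combopt import (
    HillBlissProfile,
    ObjectiveSpec,
    PanelSpec,
    TreatmentSpace,
    generate_panel,
    make_fig1_toy,
)


@pytest.fixture(scope="session")
def space7():
    return TreatmentSpace(d=7)


@pytest.fixture(scope="session")
def space2():
    return TreatmentSpace(d=2, drug_names=["a", "b"])


@pytest.fixture(scope="session")
def single_hill():
    """One-drug-dominant cell line with a simple exact half-max structure."""
    return HillBlissProfile(
        ic50=[100.0, 400.0], emax=[1.0, 0.8], hill=[1.0, 1.0], label="toy"
    )


@pytest.fixture(scope="session")
def panel2d():
    """Two heterogeneous 2-drug cell lines for grid-oracle comparisons."""
    return generate_panel(PanelSpec(n_lines=2, d=2, seed=7))


@pytest.fixture(scope="session")
def panel7d():
    return generate_panel(PanelSpec(n_lines=3, d=7, seed=11))


@pytest.fixture(scope="session")
def fig1():
    return make_fig1_toy()


@pytest.fixture
def l1_spec():
    return ObjectiveSpec(lambda_penalty=1e-4, regularizer="l1", aggregation="max")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251002)
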