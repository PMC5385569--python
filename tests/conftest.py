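import numpy as np
import pytest

from dihmm.model import DiHMMModel
from dihmm import simulate
from dihmm.types import BinarizedTracks


def random_model(
    n_nuc=2, n_dom=2, n_marks=2, block_size=2, seed=0, dirichlet=1.0
) -> DiHMMModel:
    """A random valid model (Dirichlet rows, uniform(0.05, 0.95) emissions)."""
    rng = np.random.default_rng(seed)
    E = rng.uniform(0.05, 0.95, size=(n_nuc, n_marks))
    t = rng.dirichlet(np.full(n_nuc, dirichlet), size=(n_dom, n_nuc))
    T = rng.dirichlet(np.full(n_dom, dirichlet), size=n_dom)
    P0 = rng.dirichlet(np.full(n_nuc * n_dom, dirichlet)).reshape(n_nuc, n_dom)
    return DiHMMModel(
        emissions=E,
        nuc_trans=t,
        dom_trans=T,
        initial=P0,
        block_size=block_size,
        mark_names=tuple(f"m{i}" for i in range(n_marks)),
    )


def random_tracks(model: DiHMMModel, length: int, seed=0) -> BinarizedTracks:
    """Observations drawn from the model itself (always positive likelihood)."""
    path = simulate.sample_path(model, length, seed=seed)
    return simulate.sample_observations(model, path, seed=seed)


@pytest.fixture
def toy_model() -> DiHMMModel:
    """Fixed small model (K_n=2, K_d=2, D_S=2) for enumeration-oracle tests."""
    return random_model(n_nuc=2, n_dom=2, n_marks=2, block_size=2, seed=42)


@pytest.fixture
def toy_tracks(toy_model) -> BinarizedTracks:
    return random_tracks(toy_model, 4, seed=7)


@pytest.fixture(scope="session")
def sharp_model() -> DiHMMModel:
    """Near-deterministic fixture (strong emissions, sticky transitions)."""
    return simulate.make_fixture_model(
        n_nuc=4, n_dom=2, n_marks=6, block_size=10, separation=0.49, diag=0.98
    )


@pytest.fixture(scope="session")
def recovery_model() -> DiHMMModel:
    """The parameter-recovery study fixture: K_n=4, K_d=2, M=5, D_S=10."""
    return simulate.make_fixture_model(
        n_nuc=4, n_dom=2, n_marks=5, block_size=10, separation=0.35
    )
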