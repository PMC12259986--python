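import numpy as np
import pytest

from furrowmech.engine import N_KINDS, EnergyParams, LinkSet, SimState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(rng, shape=(8, 8), n_labels=4, min_volume=3):
    """Random small lattice with every label present a few times."""
    while True:
        lattice = rng.integers(0, n_labels, shape).astype(np.int32)
        counts = np.bincount(lattice.ravel(), minlength=n_labels)
        if counts.min() >= min_volume:
            break
    kind = (np.arange(n_labels) % N_KINDS).astype(np.int8)
    return SimState.from_lattice(lattice, kind)


def random_params(rng, lam_V=1.0, lam_S=0.5, T=5.0):
    J = rng.uniform(0, 10, (N_KINDS, N_KINDS))
    J = (J + J.T) / 2
    return EnergyParams(J=J, lam_V=lam_V, lam_S=lam_S, T=T)


def random_links(rng, n_labels, n_links=3):
    labels = rng.integers(1, n_labels, (n_links, 2))
    return LinkSet(a=labels[:, 0], b=labels[:, 1],
                   lam=rng.uniform(0, 5, n_links),
                   d0=rng.uniform(0, 4, n_links),
                   kind=np.zeros(n_links, dtype=np.int64))


@pytest.fixture(scope="session")
def built_embryo():
    """One reduced-geometry initial state shared across tests."""
    from furrowmech import reduced_config
    from furrowmech.embryo import build_initial_state
    cfg = reduced_config()
    state, cells = build_initial_state(cfg.geometry)
    return cfg, state, cells
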