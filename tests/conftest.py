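import numpy as np
import pytest

import safrag as sf


@pytest.fixture(scope="session")
def model():
    """The bundled 27-letter toy alphabet."""
    return sf.load_default_model()


@pytest.fixture(scope="session")
def default_cfg():
    return sf.default_search_config()


@pytest.fixture(scope="session")
def small_bank(model):
    """Eight synthetic proteins with pseudo-predicted profiles."""
    spec = sf.BankSpec(
        n_proteins=8, min_len=30, max_len=50, prediction_concentration=50.0, seed=21
    )
    return sf.build_bank(spec, model)


@pytest.fixture(scope="session")
def toy_3state():
    """Well-separated 3-state alphabet over descriptor space, for decoder
    and EM tests."""
    means = np.array(
        [
            [5.5, 5.1, 5.5, 7.4],   # helix-like
            [6.9, 10.3, 6.9, 0.5],  # extended
            [4.5, 4.0, 4.5, -4.0],  # turn-like
        ]
    )
    covs = np.stack([np.eye(4) * 0.05 for _ in range(3)])
    trans = np.array([[0.90, 0.05, 0.05], [0.08, 0.84, 0.08], [0.10, 0.10, 0.80]])
    init = np.array([0.4, 0.35, 0.25])
    return sf.SAModel("ABC", means, covs, trans, init)


def sample_descriptor_paths(hmm_model, n_seqs, length, seed):
    """Simulate (states, descriptors) sequences from an SAModel."""
    rng = np.random.default_rng(seed)
    out = []
    k = hmm_model.n_states
    for _ in range(n_seqs):
        states = np.empty(length, dtype=int)
        states[0] = rng.choice(k, p=hmm_model.initial_probs)
        for t in range(1, length):
            states[t] = rng.choice(k, p=hmm_model.transitions[states[t - 1]])
        X = np.stack(
            [
                rng.multivariate_normal(
                    hmm_model.emission_means[s], hmm_model.emission_covariances[s]
                )
                for s in states
            ]
        )
        out.append((states, X))
    return out


@pytest.fixture(scope="session")
def random_profile_rows():
    """Deterministic batch of random normalized 27-vectors."""
    rng = np.random.default_rng(42)
    rows = rng.dirichlet(np.full(27, 0.5), size=2000)
    return rows
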