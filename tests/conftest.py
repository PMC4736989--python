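import warnings

import pytest

import semmine as sm

VTYPES = ["Compound", "Target", "Protein", "Disease"]
ETYPES = ["binds_to", "similar_to", "involved_in"]


def small_spec(n: int, seed: int) -> sm.SyntheticSpec:
    """A multi-type spec roughly mirroring a drug-discovery metagraph."""
    c = max(2, n * 3 // 10)
    t = max(2, n * 3 // 10)
    p = max(2, n // 5)
    d = max(2, n - c - t - p)
    return sm.SyntheticSpec(
        {"Compound": c, "Target": t, "Protein": p, "Disease": d},
        {
            ("Compound", "binds_to", "Target"): n,
            ("Compound", "similar_to", "Compound"): n // 2,
            ("Target", "involved_in", "Disease"): n // 2,
            ("Protein", "similar_to", "Target"): n // 3,
        },
        seed=seed,
    )


def random_instance(seed: int, n_g: int = 30, n_q: int = 4, extra: int = 1):
    """A seeded (target graph, query, matrices) triple for equivalence tests."""
    G = sm.random_graph(small_spec(n_g, seed))
    Q = sm.random_query(n_q, VTYPES, ETYPES, extra_edges=extra, seed=seed + 1000)
    M = sm.identity_sdc(VTYPES, ETYPES)
    return G, Q, M


@pytest.fixture
def fixture_graph_query():
    return sm.chlorpromazine_fixture()


@pytest.fixture
def identity_matrices():
    return sm.identity_sdc(VTYPES, ETYPES)


@pytest.fixture(autouse=True)
def _silence_anchor_fallback_warnings():
    # random queries frequently lack a Compound role; the fallback warning is
    # expected there and would otherwise drown the output
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*anchor type.*")
        yield
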