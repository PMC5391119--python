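from __future__ import annotations

import pytest

import hskel as hk


@pytest.fixture(scope="session")
def ns():
    """The worked no-signaling example system (m=24, n=14)."""
    return hk.gen_ns_example()


@pytest.fixture(scope="session")
def ns_graph(ns):
    """Full skeleton graph of the no-signaling example (computed once)."""
    return hk.skeleton_graph(ns.hrep, ns.start, test="algebraic")


@pytest.fixture(scope="session")
def small_fixtures():
    """Fixtures small enough for exhaustive cross-checks (m <= 12)."""
    return [
        hk.gen_classic("cube", 3),
        hk.gen_classic("simplex", 4),
        hk.gen_classic("crosspolytope", 3),
        hk.gen_birkhoff(3),
        hk.gen_random_regular(3, 10, 7),
    ]
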