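"""Shared fixtures: small simulated networks and the worked-example frequency maps."""

from __future__ import annotations

import pytest

from netdiff.diff import EdgeScoreMap
from netdiff.simulate import derive_pair, random_network, sample_data

#: printed per-dataset edge frequencies from the five-node worked example
#: (D1 with n=1000 from G1, D2 with n=200 from G2, skeleton mode, B=50):
#: {edge: (frequency from D1, frequency from D2)}
EXAMPLE_BS_FREQS = {
    ("D", "E"): (0.94, 0.0),
    ("A", "C"): (0.86, 0.1),
    ("B", "C"): (1.0, 1.0),
    ("C", "D"): (1.0, 1.0),
    ("A", "D"): (0.04, 0.02),
    ("B", "E"): (0.24, 0.0),
}
#: same, with D1 scored by equal-size subsamples at n=200 instead of bootstrap
EXAMPLE_RSBS_FREQS = {
    ("D", "E"): (0.42, 0.0),
    ("A", "C"): (0.16, 0.1),
    ("B", "C"): (1.0, 1.0),
    ("C", "D"): (1.0, 1.0),
    ("A", "D"): (0.04, 0.02),
    ("B", "E"): (0.04, 0.0),
}
EXAMPLE_VARIABLES = ("A", "B", "C", "D", "E")


def _freq_maps(table):
    f1 = EdgeScoreMap(
        mode="skeleton",
        variables=EXAMPLE_VARIABLES,
        scores={e: v1 for e, (v1, _) in table.items() if v1},
        resample_count=50,
    )
    f2 = EdgeScoreMap(
        mode="skeleton",
        variables=EXAMPLE_VARIABLES,
        scores={e: v2 for e, (_, v2) in table.items() if v2},
        resample_count=50,
    )
    return f1, f2


@pytest.fixture(scope="session")
def example_bs_freqs():
    return _freq_maps(EXAMPLE_BS_FREQS)


@pytest.fixture(scope="session")
def example_rsbs_freqs():
    return _freq_maps(EXAMPLE_RSBS_FREQS)


@pytest.fixture(scope="session")
def small_net():
    """A 10-node, 20-edge unit-marginal network."""
    return random_network(10, 20, seed=11)


@pytest.fixture(scope="session")
def small_pair(small_net):
    return derive_pair(small_net, 5, seed=13)


@pytest.fixture(scope="session")
def small_data(small_net):
    return sample_data(small_net, 500, seed=17)
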