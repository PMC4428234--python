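import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from ccmds import make_figure1_fixture, random_network


@pytest.fixture(scope="session")
def fig1():
    """The 10-node toy network with four minimum dominating sets."""
    return make_figure1_fixture()


def connected_er(n: int, p: float, seed: int):
    """First fully connected G(n, p) draw at or after ``seed`` (deterministic)."""
    for t in range(100):
        net = random_network("uniform-random", n, p, seed=seed * 100 + t)
        if net.n == n:
            return net
    raise RuntimeError(f"no connected G({n},{p}) found near seed {seed}")


@pytest.fixture(scope="session")
def small_random_networks():
    """200 seeded connected graphs with n in [4, 12] for oracle comparisons."""
    nets = []
    for seed in range(100):
        n = 4 + seed % 9
        nets.append(connected_er(n, 0.45, seed))
        nets.append(random_network("preferential-attachment", n, 2, seed=seed))
    return nets
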