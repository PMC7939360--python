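import numpy as np
import pytest

from idrslab.forcefield import Configuration, ModelParams, Topology
from idrslab.sequences import assign_charges


@pytest.fixture
def params_10mm() -> ModelParams:
    return ModelParams(c_salt=0.01)


@pytest.fixture
def params_screened() -> ModelParams:
    return ModelParams(c_salt="screened")


def random_system(
    seed: int,
    n_chains: int = 4,
    chain_length: int = 10,
    box=(10.0, 10.0, 10.0),
    charged: bool = True,
    min_sep: float = 0.4,
):
    """Seeded random chains with bond length 0.38 and no hard clashes.

    Walks use correlated step directions so 1-3 neighbors stay apart;
    *min_sep* is enforced for all pairs other than same-chain |i-j| <= 2.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if charged:
        letters = rng.choice(list("EKGASDPR"), size=chain_length)
        seq = assign_charges("".join(letters))
    else:
        seq = assign_charges("G" * chain_length)
    topo = Topology.from_sequence(seq, n_chains)
    from oracles import min_image

    for _ in range(500):
        pos = np.empty((topo.n_beads, 3))
        for c in range(n_chains):
            start = rng.uniform(0, 1, 3) * box
            pos[c * chain_length] = start
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            for i in range(1, chain_length):
                u = u + 0.6 * rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos[c * chain_length + i] = pos[c * chain_length + i - 1] + 0.38 * u
        config = Configuration(pos, box)
        chain = topo.chain_of_bead
        ok = True
        w = config.wrapped()
        for i in range(topo.n_beads):
            for j in range(i + 1, topo.n_beads):
                if chain[i] == chain[j] and j - i <= 2:
                    continue
                r = np.linalg.norm(min_image(w[j] - w[i], box))
                if r < min_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return topo, config
    raise RuntimeError("could not build a clash-free random system")
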