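import numpy as np
import pytest

from npbench.model import PpiGraph, TripartiteNetwork, compound, herb, target


@pytest.fixture
def toy_tripartite() -> TripartiteNetwork:
    """H1-{C1,C2}, H2-C1; C1-{T1,T2}, C2-T1 — the worked DWPC fixture."""
    return TripartiteNetwork(
        db_label="toy",
        hc_edges={(herb("H1"), compound(1)), (herb("H1"), compound(2)),
                  (herb("H2"), compound(1))},
        ct_edges={(compound(1), target(10)), (compound(1), target(11)),
                  (compound(2), target(10))},
    )


@pytest.fixture
def path_graph() -> PpiGraph:
    """The 3-node path a-b-c."""
    a, b, c = target(1), target(2), target(3)
    return PpiGraph(edges=[(a, b), (b, c)])


def random_tripartite(rng: np.random.Generator, n_h=4, n_c=8, n_t=10,
                      p_hc=0.4, p_ct=0.3, label="rnd") -> TripartiteNetwork:
    """Small random tripartite network for oracle comparisons."""
    herbs = [herb(f"H{i}") for i in range(n_h)]
    compounds = [compound(100 + i) for i in range(n_c)]
    targets = [target(500 + i) for i in range(n_t)]
    hc = {(h, c) for h in herbs for c in compounds if rng.random() < p_hc}
    ct = {(c, t) for c in compounds for t in targets if rng.random() < p_ct}
    return TripartiteNetwork(db_label=label, hc_edges=hc, ct_edges=ct)
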