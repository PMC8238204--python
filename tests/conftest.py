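import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prer.network import PPINetwork
from prer.simulate import SimConfig, simulate_cohort, simulate_network
from prer.survival import SurvivalData


def make_net(edges, default_conf=1.0):
    """Build a PPINetwork from (u, v[, conf]) tuples."""
    g = nx.Graph()
    for e in edges:
        u, v, *rest = e
        conf = rest[0] if rest else default_conf
        g.add_edge(u, v, confidence=conf, weight=1.0)
    return PPINetwork(g)


@pytest.fixture
def path_net():
    return make_net([("t", "v"), ("v", "x")])


@pytest.fixture
def edge_file(tmp_path):
    def write(rows, name="edges.tsv"):
        p = tmp_path / name
        p.write_text("".join(r + "\n" for r in rows))
        return p

    return write


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by the slower integration tests."""
    cfg = SimConfig(n_proteins=200, n_measured=24, n_patients=120, seed=11)
    net = simulate_network(cfg)
    expr, surv, truth = simulate_cohort(net, cfg)
    return net, expr, surv, truth, cfg


def random_survival(rng, n, censor=0.3):
    time = rng.exponential(1.0, n) + 1e-3
    event = rng.random(n) > censor
    if event.sum() < 2:  # guarantee comparable pairs
        event[:2] = True
    return SurvivalData(time, event)
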