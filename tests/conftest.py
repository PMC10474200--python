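import pandas as pd
import pytest

from causalsig import RegulatoryNetwork, SimulationConfig, generate_deg_table, generate_network


@pytest.fixture
def star_net() -> RegulatoryNetwork:
    """TF T activates ten genes directly (all transcription edges)."""
    net = RegulatoryNetwork()
    net.add_node("T", "TF")
    for i in range(10):
        g = f"D{i}"
        net.add_node(g, "other")
        net.add_edge("T", g, 1, "transcription-regulation")
    return net


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": ["A", "B", "C"],
            "log2fc": [2.5, -1.0, 3.0],
            "pvalue": [0.001, 0.001, 0.05],
            "fdr": [0.01, 0.01, 0.2],
        }
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One small synthetic study shared across read-only tests."""
    cfg = SimulationConfig(seed=11, network_size=250, n_genes=400)
    net = generate_network(cfg)
    table, truth = generate_deg_table(net, cfg)
    return cfg, net, table, truth
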