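import numpy as np
import pandas as pd
import pytest

from phagenet import (CommunityDesign, build_master_network,
                      default_domain_table, extract_sample_graph,
                      generate_community, generate_genomes,
                      generate_truth_network)


@pytest.fixture(scope="session")
def domain_table():
    return default_domain_table()


@pytest.fixture(scope="session")
def genome_pair():
    """One unrelated phage/bacterium pair (the null background)."""
    phage, = generate_genomes(1, "phage", (5000, 6000), seed=11)
    bacterium, = generate_genomes(1, "bacterium", (5000, 6000), seed=12)
    return phage, bacterium


def make_sample_graphs(rep: int, design: CommunityDesign | None = None,
                       n_phages: int = 30, n_bacteria: int = 45,
                       density: float = 0.8):
    """Build per-sample graphs from one synthetic community replicate."""
    truth = generate_truth_network(n_phages, n_bacteria, density,
                                   seed=10_000 + rep)
    phages, bacts, edges = truth
    roles = {**{p: "phage" for p in phages},
             **{b: "bacterium" for b in bacts}}
    pred = pd.DataFrame(edges, columns=["phage_id", "bacterium_id"])
    pred["prediction"] = "interacts"
    design = design or CommunityDesign()
    abundance, metadata = generate_community(design, truth,
                                             seed=20_000 + rep)
    master = build_master_network(pred, abundance, roles, metadata)
    graphs = {s: extract_sample_graph(master, s)
              for s in abundance.columns}
    return master, graphs, metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
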