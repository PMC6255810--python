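import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phosphonet.simulate import SyntheticScenario, simulate_all

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory, default_scenario):
    """Synthetic input bundle: (directory, truth dict)."""
    outdir = tmp_path_factory.mktemp("synth")
    truth = simulate_all(default_scenario, outdir)
    with open(outdir / "truth.json") as fh:
        truth_json = json.load(fh)
    return outdir, truth, truth_json


@pytest.fixture(scope="session")
def pipeline_config(synth_bundle):
    outdir, _, _ = synth_bundle
    return {
        "inputs": {
            "network": str(outdir / "network.sif"),
            "phospho_signals": str(outdir / "phospho_signals.tsv"),
            "effects": str(outdir / "effects.tsv"),
            "kinases": str(outdir / "kinases.tsv"),
            "regulons": str(outdir / "regulons.tsv"),
            "signature": str(outdir / "signature.tsv"),
            "categories": str(outdir / "categories.gmt"),
        },
        "labels": {
            "control": "CONTROL",
            "treatments": ["BMP8", "NE", "BMP8_NE"],
            "focal_treatment": "BMP8",
        },
        "genes_of_interest": ["TGT1"],
        "seed": 1,
    }


@pytest.fixture
def small_fcs():
    """Sign-adjusted fold-change table with hand-checkable values."""
    return pd.DataFrame({
        "protein": ["AKT1", "AKT1", "TP53", "TP53", "MEF2A"],
        "site": ["S473", "T308", "S15", "S20", "T312"],
        "treatment": ["BMP8", "BMP8", "BMP8", "NE", "NE"],
        "log2fc": [1.5, -0.2, 0.9, -1.4, 0.1],
        "adjusted_log2fc": [1.5, 0.2, -0.9, -1.4, 0.1],
    })


@pytest.fixture
def effects_table():
    return pd.DataFrame({
        "protein": ["AKT1", "AKT1", "TP53"],
        "site": ["S473", "T308", "S15"],
        "sign": [1, -1, 0],
        "partners": [(("GRB2", "induce"),), (), (("MDM2", "disrupt"), ("EP300", "induce"))],
    })


def random_digraph_edges(rng, n_nodes, n_edges, no_dangling=False):
    """Random directed graph helper shared by network tests."""
    nodes = [f"G{i:03d}" for i in range(n_nodes)]
    n_edges = min(n_edges, n_nodes * (n_nodes - 1) // 2)  # keep rejection sampling fast
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            edges.add((nodes[i], nodes[j]))
    if no_dangling:
        sources = {s for s, _ in edges}
        for node in nodes:
            if node not in sources:
                tgt = nodes[(nodes.index(node) + 1) % n_nodes]
                edges.add((node, tgt))
    return nodes, sorted(edges)
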