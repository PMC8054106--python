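import numpy as np
import pandas as pd
import pytest

from prevsmooth import RegionGraph, make_reference_scenario
from prevsmooth.survey import assemble_dataset, estimate_observations


@pytest.fixture
def pair_graph():
    """Two regions joined by one edge."""
    return RegionGraph(("A", "B"), frozenset({frozenset({"A", "B"})}))


@pytest.fixture
def path_graph():
    """Path A - B - C."""
    return RegionGraph.from_edge_list([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def ref_scenario():
    return make_reference_scenario(seed=1)


@pytest.fixture(scope="session")
def ref_dataset(ref_scenario):
    obs = estimate_observations(
        ref_scenario.microdata, ref_scenario.survey_years
    )
    return assemble_dataset(obs, ref_scenario.graph, ref_scenario.years)


def random_connected_graph(rng: np.random.Generator, k: int) -> RegionGraph:
    """Random spanning tree plus random extra edges; always connected."""
    labels = [f"N{i}" for i in range(k)]
    edges = set()
    order = rng.permutation(k)
    for i in range(1, k):
        j = order[rng.integers(0, i)]
        edges.add(frozenset((labels[order[i]], labels[j])))
    for _ in range(rng.integers(0, k)):
        a, b = rng.choice(k, size=2, replace=False)
        edges.add(frozenset((labels[a], labels[b])))
    return RegionGraph(tuple(labels), frozenset(edges))


def micro_frame(rows):
    """Microdata DataFrame from (survey, family, region, year, outcome, weight, cluster)."""
    return pd.DataFrame(
        rows,
        columns=[
            "survey_id",
            "survey_family",
            "region_id",
            "event_year",
            "outcome",
            "weight",
            "cluster_id",
        ],
    )
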