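import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import symptomnet as sn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_network():
    """The published 24-node burnout-depression network (corrected transcription)."""
    return sn.load_fixture_network()


@pytest.fixture(scope="session")
def item_info():
    return sn.load_item_info()


@pytest.fixture(scope="session")
def study_cohort(fixture_network, item_info):
    """Synthetic cohort emulating the study: n=616, published network + moments."""
    spec = sn.CohortSpec.from_network_and_moments(fixture_network, item_info, n=616, seed=0)
    return sn.simulate_cohort(spec)


def four_node_chain(w: float = 0.4) -> sn.NetworkModel:
    """Tiny two-community network: one strong within edge, weak bridges."""
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = w
    W[1, 2] = W[2, 1] = 0.15
    W[2, 3] = W[3, 2] = 0.25
    return sn.NetworkModel(
        node_ids=("MBI1", "MBI2", "PHQ1", "PHQ2"),
        weights=W,
        communities={"MBI1": "burnout", "MBI2": "burnout", "PHQ1": "depression", "PHQ2": "depression"},
    )


def simulate_four_node(n: int, seed: int, w: float = 0.4) -> pd.DataFrame:
    """Ordinal cohort from the 4-node chain with mid-scale thresholds."""
    net = four_node_chain(w)
    sigma = sn.network_to_latent_sigma(net)
    thresholds = {
        item: sn.calibrate_thresholds(
            mean=3.0 if item.startswith("MBI") else 1.5,
            sd=1.4 if item.startswith("MBI") else 0.9,
            n_categories=7 if item.startswith("MBI") else 4,
            item_id=item,
        )[0]
        for item in net.node_ids
    }
    spec = sn.CohortSpec(
        n=n, item_ids=net.node_ids, latent_sigma=sigma, thresholds=thresholds, seed=seed
    )
    return sn.simulate_cohort(spec).data


@pytest.fixture(scope="session")
def four_node_cohort():
    return simulate_four_node(n=1000, seed=42)
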