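import numpy as np
import pytest

import proxistate as px


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable 9-fragment bundle."""
    return px.toy_fixture()


@pytest.fixture(scope="session")
def bundle():
    """One default-condition synthetic bundle, shared across tests."""
    return px.simulate(px.default_config(), seed=1)


@pytest.fixture(scope="session")
def pair_table(bundle):
    return px.build_pair_table(
        bundle.proximity,
        tracks={k: bundle.tracks[k]
                for k in ("expression", "DNAse", "methylation")},
        states=bundle.states, n_states=bundle.config.n_states,
        genes=bundle.genes, go_graphs={"CC": bundle.go_graphs["CC"]},
        links=bundle.links)


@pytest.fixture(scope="session")
def prox_bins(pair_table):
    return px.make_proximity_bins(pair_table["proximity"].to_numpy())
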