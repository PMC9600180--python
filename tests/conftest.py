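"""Shared fixtures: small synthetic communities generated at test time."""

import numpy as np
import pandas as pd
import pytest

from raresoil import (
    CommunityConfig,
    OtuTable,
    classify_taxa,
    default_scenarios,
    generate_initial_community,
    relative_abundance,
    simulate_disturbance_series,
)


@pytest.fixture(scope="session")
def small_config():
    return CommunityConfig(n_otus=600, depth=4_000, seed=11)


@pytest.fixture(scope="session")
def small_initial(small_config):
    return generate_initial_community(small_config)


@pytest.fixture(scope="session")
def small_series(small_config, small_initial):
    """Full disturbance x timepoint layout on a small community."""
    return simulate_disturbance_series(small_initial, default_scenarios(), small_config)


@pytest.fixture(scope="session")
def ncf_rel(small_series):
    rel = relative_abundance(small_series)
    ids = small_series.metadata.index[small_series.metadata["soil"] == "NCF"]
    return rel.subset_samples(ids)


@pytest.fixture(scope="session")
def ncf_assignment(small_series):
    rel = relative_abundance(small_series)
    return classify_taxa(rel.subset_samples(small_series.initial_samples("NCF")))


def toy_table(counts, soils=None, timepoints=None, treatments=None):
    """Build a small OtuTable from a dense array for hand-computed cases."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    sids = [f"S{j}" for j in range(n_samples)]
    md = pd.DataFrame(
        {
            "soil": soils or ["NCF"] * n_samples,
            "treatment": treatments or ["none"] * n_samples,
            "timepoint": timepoints or ["initial"] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=sids,
    )
    return OtuTable(
        pd.DataFrame(counts, index=[f"O{i}" for i in range(n_otus)], columns=sids), md
    )
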