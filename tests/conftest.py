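import numpy as np
import pandas as pd
import pytest

from lncoop.synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_clinical,
    generate_omics_bundle,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_config):
    """One full synthetic study at default conditions (seed 0)."""
    bundle, truth = generate_omics_bundle(default_config)
    genesets, ppi = generate_annotation(default_config)
    infiltration, clinical = generate_clinical(default_config, bundle, truth)
    return {
        "config": default_config,
        "bundle": bundle,
        "truth": truth,
        "genesets": genesets,
        "ppi": ppi,
        "infiltration": infiltration,
        "clinical": clinical,
    }


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]],
        index=["f1", "f2"],
        columns=["s1", "s2"],
    )
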