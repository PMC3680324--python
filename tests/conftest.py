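import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from clustermir import RunConfig, SimulationSpec


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def small_spec() -> SimulationSpec:
    """A desk-scale simulation: 60 features, 8-member cluster, 10+10 samples."""
    return SimulationSpec(
        n_features=60, cluster_size=8, n_case=10, n_control=10, seed=42
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_ct_table(rows, references=("ref",), groups=None):
    """Build a CtTable from (sample, assay, replicate, ct) tuples."""
    from clustermir import CtTable

    wells = pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "ct"])
    if groups is None:
        groups = {
            s: ("case" if s.startswith("case") else "control")
            for s in wells["sample_id"].unique()
        }
    return CtTable(
        wells=wells,
        reference_assays=list(references),
        group=pd.Series(groups),
    )
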