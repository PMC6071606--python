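from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from herscan.simdata import default_marker_map

DATA_DIR = Path(__file__).resolve().parents[1] / "data"


@pytest.fixture(scope="session")
def tiny_map():
    """Small default-karyotype map (80 probes per chromosome)."""
    return default_marker_map(n_probes_per_chromosome=80)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reference_chromosome_counts() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "reference_chromosome_counts.tsv",
                       sep="\t", comment="#")


@pytest.fixture(scope="session")
def reference_her_pairs() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "reference_her_pairs.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def reference_line_counts() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "reference_line_counts.tsv", sep="\t", comment="#")
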