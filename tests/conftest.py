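import pandas as pd
import pytest

from exrnatools import AbundanceTable, SimConfig, generate_experiment

BASE_COLUMNS = [
    "species_id",
    "rna_class",
    "culture_id",
    "fraction",
    "library",
    "read_count",
]


def build_table(rows, with_fmol=False):
    """Rows of (species, class, culture, fraction, library, count[, fmol])."""
    cols = BASE_COLUMNS + (["fmol_per_ug"] if with_fmol else [])
    return AbundanceTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def make_table():
    return build_table


@pytest.fixture(scope="session")
def default_dataset():
    """One realized synthetic experiment at the default study conditions
    (4 cultures, default class panel), with an FM background species."""
    config = SimConfig(seed=7, fm_background={"miR-122-like": 5.0})
    return config, generate_experiment(config)
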