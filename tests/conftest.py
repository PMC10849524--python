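import numpy as np
import pandas as pd
import pytest

from histoquant.masscalc import BACKBONES, MSConfig
from histoquant.proteoform_space import enumerate_proteoforms, isobaric_classes, load_schema


@pytest.fixture(scope="session")
def h4_backbone():
    return BACKBONES["H4"]


@pytest.fixture(scope="session")
def h3_backbone():
    return BACKBONES["H3.2_tail"]


@pytest.fixture(scope="session")
def h4_schema():
    return load_schema("H4")


@pytest.fixture(scope="session")
def h3_schema():
    return load_schema("H3.2")


@pytest.fixture(scope="session")
def ms_config():
    return MSConfig()


@pytest.fixture(scope="session")
def h4_space(h4_schema):
    return enumerate_proteoforms(h4_schema)


@pytest.fixture(scope="session")
def h4_classes(h4_space, ms_config, h4_schema):
    return isobaric_classes(h4_space, ms_config, h4_schema)


def make_abundance_table(entries, family="H4", tissue="BAT", condition="RT"):
    """Build a one-sample-per-dict abundance table from
    {sample: {notation: percent}} entries; caller guarantees sums of 100."""
    rows = []
    for sample, props in entries.items():
        for notation, ab in props.items():
            rows.append((family, notation, sample, condition, tissue, ab))
    return pd.DataFrame(
        rows,
        columns=["family", "proteoform", "sample", "condition", "tissue", "abundance_percent"],
    )
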