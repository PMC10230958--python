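import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rootplast.trait_data import LONG_COLUMNS, PhenotypeTable, load_table1_fixture, table1_registry

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return table1_registry()


@pytest.fixture(scope="session")
def fixture_table():
    return load_table1_fixture()


def plot_table(rows) -> PhenotypeTable:
    """Build a plot-level PhenotypeTable from (genotype, p_rate, plot, value)
    tuples (optionally (genotype, p_rate, run, block, plot, value))."""
    recs = []
    for r in rows:
        if len(r) == 4:
            g, p, plot, v = r
            run = block = 1
        else:
            g, p, run, block, plot, v = r
        recs.append(
            {
                "genotype": g,
                "p_rate": float(p),
                "run": run,
                "block": block,
                "plot": plot,
                "plant": 0,
                "view": 0,
                "trait": "T",
                "value": float(v),
            }
        )
    df = pd.DataFrame(recs, columns=list(LONG_COLUMNS))
    return PhenotypeTable(df, level="plot")
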