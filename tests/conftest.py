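import numpy as np
import pytest

from riscreen.pesticide_db import collapse_isomers
from riscreen.synthetic import (
    annotated_reference_panel,
    default_curves,
    fixture_tables,
    printed_annotated_panel,
    reference_ladder_fit,
)


@pytest.fixture(scope="session")
def tables():
    return fixture_tables()


@pytest.fixture(scope="session")
def panel_records(tables):
    return list(tables.panel)


@pytest.fixture(scope="session")
def ladder_fit():
    return reference_ladder_fit()


@pytest.fixture(scope="session")
def annotated_panel():
    return annotated_reference_panel()


@pytest.fixture(scope="session")
def printed_panel():
    return printed_annotated_panel()


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def make_ladder_pairs(ladder, n_per_segment=8, rng=None):
    """Dense exact (RI, RT) samples of a ladder, for recovery tests."""
    from riscreen.ri_core import compute_retention_index

    rng = rng or np.random.default_rng(0)
    pairs = []
    times = ladder.times
    for lo, hi in zip(times[:-1], times[1:]):
        for rt in np.linspace(lo, hi, n_per_segment + 2)[1:-1]:
            pairs.append((compute_retention_index(ladder, rt), float(rt)))
    return pairs
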