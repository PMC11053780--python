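import warnings

import pytest

from bbkit import io


@pytest.fixture(scope="session")
def contact_tables():
    """Hirshfeld contact tables keyed by structure id.

    A couple of printed rows carry documented inconsistencies (totals off
    100 by up to 1.6%); silence those known warnings for the whole suite.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        tables = io.load_fixture("contact_tables")
    return {t.structure_id: t for t in tables}


@pytest.fixture(scope="session")
def surface_proportions():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return io.load_fixture("surface_proportions")


@pytest.fixture(scope="session")
def dck_panel():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # one positive printed energy
        return io.load_fixture("dck_panel")


@pytest.fixture(scope="session")
def frontier():
    return {f.ligand_id: f for f in io.load_fixture("frontier")}


@pytest.fixture(scope="session")
def frontier_table():
    return io.load_fixture("frontier_table")
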