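import numpy as np
import pandas as pd
import pytest

from landghg.synthetic import SyntheticConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A 60x60, 4-region synthetic landscape shared across tests."""
    return generate_landscape(SyntheticConfig(seed=42, shape=(60, 60), n_regions=4))


@pytest.fixture(scope="session")
def national_tables():
    from landghg.national_tables import load_area_table, load_flux_table, load_region_table
    return {"t1": load_area_table(), "t2": load_flux_table(), "t3": load_region_table()}


@pytest.fixture(scope="session")
def published_report():
    from landghg.national_tables import published_tables_report
    return published_tables_report()
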