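import numpy as np
import pandas as pd
import pytest

from nichepack.pipeline import ComparisonConfig, run_comparison
from nichepack.simulate import study_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """The bundled deterministic two-community dataset."""
    return study_fixture()


@pytest.fixture(scope="session")
def fixture_report(fixture_data):
    """One full pipeline run on the bundled dataset (shared across tests)."""
    config = ComparisonConfig(seed=11, n_reps=200, n_posterior_draws=3000)
    return run_comparison(
        fixture_data["forest_traits"], fixture_data["savannah_traits"],
        fixture_data["forest_isotopes"], fixture_data["savannah_isotopes"],
        config,
    )


def make_trait_frame(n_species=6, seed=0, site="siteA", group="clutter"):
    """Small valid specimen trait table for I/O and regression tests."""
    from nichepack.io import TRAIT_NAMES

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_species):
        mass = float(rng.uniform(5, 30))
        for s in range(2):
            row = {
                "specimen_id": f"sp{i}_s{s}",
                "species": f"sp{i}",
                "site": site,
                "foraging_group": group,
                "body_mass": mass,
            }
            for j, t in enumerate(TRAIT_NAMES):
                row[t] = 5 + j + 0.5 * mass + rng.normal(0, 0.5)
            rows.append(row)
    return pd.DataFrame(rows)
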