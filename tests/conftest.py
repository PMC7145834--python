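import logging

import numpy as np
import pandas as pd
import pytest

import reeftrend as rt
from reeftrend.survey_io import CommunityMatrix

logging.getLogger("reeftrend").setLevel(logging.ERROR)


def make_matrix(dens_rows, taxa, meta_rows=None, guilds=None, schooling=None):
    """Hand-build a CommunityMatrix from a list of density rows."""
    n = len(dens_rows)
    ids = [f"x{i}" for i in range(n)]
    if meta_rows is None:
        meta_rows = [{"site": f"S{i % 2}", "year": 2011, "month": 7,
                      "year_bin": "2011", "depth_m": 30.0 + i,
                      "longitude": -86.0 - 0.1 * i, "area_m2": 200.0}
                     for i in range(n)]
    dens = pd.DataFrame(dens_rows, columns=taxa, index=ids, dtype=float)
    meta = pd.DataFrame(meta_rows, index=ids)
    registry = pd.DataFrame({
        "guild": guilds or ["reef planktivore"] * len(taxa),
        "schooling": schooling or [False] * len(taxa),
    }, index=taxa)
    return CommunityMatrix(densities=dens, meta=meta, registry=registry)


@pytest.fixture(scope="session")
def small_design():
    return rt.generate_design(
        n_sites=6, years=[2009, 2010, 2011],
        months_by_year={2009: [7, 10], 2010: [4, 11], 2011: [7, 10]}, seed=11)


@pytest.fixture(scope="session")
def disturbed_community(small_design):
    params = rt.guild_scenario_params()[:5]
    patch = rt.disturbance_scenario({"herbivore": 0.8}, "2010")
    return rt.generate_community(small_design, patch.apply(params), seed=21)


@pytest.fixture(scope="session")
def full_community():
    """Study-scale multi-species community with the stock guild declines."""
    design = rt.generate_design(n_sites=10, seed=5)
    params = rt.default_community_params()
    patch = rt.disturbance_scenario(
        {"herbivore": 0.96, "small demersal browser": 0.87}, "2010")
    return rt.generate_community(design, patch.apply(params), seed=9)
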