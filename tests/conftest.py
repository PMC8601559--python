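"""Shared synthetic fixtures; everything is generated in-process."""

import numpy as np
import pandas as pd
import pytest

from landgrad.raster import CategoricalRaster, GridGeoref
from landgrad.smoothing import smooth_stack
from landgrad.synthland import LandscapeRecipe, generate_landscape


@pytest.fixture(scope="session")
def three_class_city():
    """Seeded 200x200 landscape: forest matrix, crop belt, urban core."""
    georef = GridGeoref(0.0, 6000.0, 30.0, 200, 200)
    recipe = LandscapeRecipe(
        {41: 0.5, 82: 0.3, 22: 0.2},
        center_xy=(3000.0, 3000.0),
        urban_decay=1500.0,
        autocorr_scale=150.0,
        seed=7,
    )
    return generate_landscape(recipe, georef)


@pytest.fixture(scope="session")
def sector_city():
    """Deterministic city: urban disk at center, forest west, crop east.

    The core mixes two developed intensity classes (as co-occurring
    developed cover does), so the clean sector geometry yields the
    triangular hard/soft x brown/green structure with a dominant
    development axis.
    """
    n, cell = 160, 30.0
    georef = GridGeoref(0.0, n * cell, cell, n, n)
    rows, cols = np.indices((n, n))
    rng = np.random.default_rng(11)
    values = np.where(cols < n // 2, 41, 82)  # forest west, crop east
    # speckle so no class is spatially constant within its sector
    speckle = rng.random((n, n)) < 0.08
    values = np.where(speckle, np.where(values == 41, 82, 41), values)
    r2 = (rows - n / 2) ** 2 + (cols - n / 2) ** 2
    core = r2 < (0.30 * n) ** 2
    dev = np.where(rng.random((n, n)) < 0.5, 22, 23)
    values = np.where(core, dev, values)  # urban core, two intensities
    return CategoricalRaster(georef, values.astype(np.int64))


@pytest.fixture(scope="session")
def sector_stack(sector_city):
    return smooth_stack(sector_city, [22, 23, 41, 82], sigma=300.0)


@pytest.fixture(scope="session")
def fifteen_class_city():
    """Seeded landscape using all fifteen land-cover classes."""
    from landgrad.synthland import DEFAULT_NLCD_RECIPE

    georef = GridGeoref(0.0, 3600.0, 30.0, 120, 120)
    recipe = LandscapeRecipe(
        DEFAULT_NLCD_RECIPE,
        center_xy=(1800.0, 1800.0),
        urban_decay=900.0,
        autocorr_scale=150.0,
        seed=3,
    )
    return generate_landscape(recipe, georef)


@pytest.fixture()
def checklist_table():
    """Ten checklists, three violating the survey filters."""
    rows = [
        # checklist_id, site_id, city, x, y, date, protocol, complete, detected
        ("c01", "s1", "worcester", 100.0, 900.0, "2018-04-05", "stationary", True, 1),
        ("c02", "s1", "worcester", 100.0, 900.0, "2018-04-15", "stationary", True, 0),
        ("c03", "s2", "worcester", 400.0, 700.0, "2018-05-01", "stationary", True, 0),
        ("c04", "s2", "worcester", 400.0, 700.0, "2018-06-10", "stationary", True, 1),
        ("c05", "s3", "lincoln", 800.0, 300.0, "2018-07-04", "stationary", True, 0),
        ("c06", "s3", "lincoln", 800.0, 300.0, "2018-03-20", "stationary", True, 1),  # too early
        ("c07", "s4", "lincoln", 850.0, 350.0, "2018-05-05", "traveling", True, 1),  # protocol
        ("c08", "s5", "lincoln", 900.0, 200.0, "2018-08-08", "stationary", False, 0),  # incomplete
        ("c09", "s6", "lincoln", 950.0, 250.0, "2018-09-30", "stationary", True, 1),
        ("c10", "s6", "lincoln", 950.0, 250.0, "2018-09-01", "stationary", True, 0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "checklist_id", "site_id", "city", "x", "y",
            "date", "protocol", "complete", "detected",
        ],
    )
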