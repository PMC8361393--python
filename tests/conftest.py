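"""Shared fixtures: small sensor tables, planted networks, RNG helpers."""

import numpy as np
import pandas as pd
import pytest

from ieegnet.types import SENSOR_COLUMNS


def make_sensors(rows):
    """Build a sensor table from (id, x, y, z, type, tissue, roi, hemi, resected)."""
    return pd.DataFrame(rows, columns=list(SENSOR_COLUMNS))


@pytest.fixture
def tiny_sensors():
    """5 contacts: 3 GM (one resected), 2 WM, mixed types and hemispheres."""
    return make_sensors([
        ("a", 50.0, 10.0, 0.0, "surface", "GM", "right_ant_sup_cortical", "right", False),
        ("b", 50.0, -10.0, 0.0, "surface", "GM", "right_mid_sup_cortical", "right", False),
        ("c", 25.0, 18.0, -10.0, "depth", "GM", "right_ant_inf_mesial", "right", True),
        ("d", 30.0, 18.0, -10.0, "depth", "WM", "right_ant_inf_mesial", "right", True),
        ("e", -50.0, 0.0, 0.0, "surface", "WM", "left_mid_sup_cortical", "left", False),
    ])


def random_symmetric(n, rng, low=0.0, high=1.0):
    a = rng.uniform(low, high, (n, n))
    a = np.triu(a, 1)
    a = a + a.T
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
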