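import numpy as np
import pandas as pd
import pytest

from smfishq.core import CellOutline, FieldOfViewMeta


@pytest.fixture
def meta():
    return FieldOfViewMeta(field_id="f0", case_id="c0")


@pytest.fixture
def small_meta():
    return FieldOfViewMeta(
        field_id="f0", width_px=100, height_px=100, pixel_size_nm=125.0,
        n_planes=5, plane_spacing_um=0.4, case_id="c0",
    )


@pytest.fixture
def unit_square():
    return CellOutline(
        cell_id="a", field_id="f0",
        vertices=((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)),
    )


def spot_df(rows):
    """rows of (field_id, channel, x, y, plane)."""
    return pd.DataFrame(rows, columns=["field_id", "channel", "x_px", "y_px", "plane"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
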