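import numpy as np
import pandas as pd
import pytest

from splitkit import LocalizationTable, Rectangle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Ten localizations on a 1000x1000 nm field across frames 1-5."""
    rng = np.random.default_rng(7)
    return LocalizationTable.from_arrays(
        frame=rng.integers(1, 6, 10),
        x=rng.uniform(0, 1000, 10),
        y=rng.uniform(0, 1000, 10),
        photons=rng.uniform(100, 3000, 10),
        bounds=Rectangle(0, 1000, 0, 1000),
    )


def make_pairs(i_s, i_l, x_s=None, y_s=None, x_l=None, y_l=None, frame=None):
    """Assemble a pair DataFrame from photon counts and optional coordinates."""
    i_s = np.asarray(i_s, dtype=float)
    i_l = np.asarray(i_l, dtype=float)
    n = len(i_s)
    zeros = np.zeros(n)
    df = pd.DataFrame(
        {
            "frame": np.ones(n, dtype=np.int64) if frame is None else frame,
            "x_s": zeros if x_s is None else np.asarray(x_s, float),
            "y_s": zeros if y_s is None else np.asarray(y_s, float),
            "x_l": zeros if x_l is None else np.asarray(x_l, float),
            "y_l": zeros if y_l is None else np.asarray(y_l, float),
            "i_s": i_s,
            "i_l": i_l,
        }
    )
    df["r"] = df["i_l"] / df["i_s"]
    return df
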