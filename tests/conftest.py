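import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_loc_table():
    """Four localizations: two tight pairs far apart."""
    return pd.DataFrame({
        "x_nm": [0.0, 5.0, 1000.0, 1004.0],
        "y_nm": [0.0, 0.0, 0.0, 3.0],
        "frame": [0, 1, 2, 3],
        "precision_nm": [20.0, 20.0, 15.0, 15.0],
    })
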