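import numpy as np
import pytest

from polytrans import GradientModel, simulate_profile


@pytest.fixture
def default_model():
    return GradientModel()


@pytest.fixture
def separated_model():
    """Peaks far apart relative to their widths: region integration is exact."""
    return GradientModel(
        peak_centers=(1.0, 2.5, 4.0, 5.5, 7.0, 8.5),
        peak_widths=(0.15,) * 6,
        peak_amplitudes=(0.9, 0.4, 0.5, 1.2, 1.0, 0.6))


@pytest.fixture
def noiseless_profile(default_model):
    return simulate_profile(default_model, seed=0)


@pytest.fixture
def mouse_table():
    """6-mouse (FRP, relative weight, relative righting) fixture used by the
    clustering tests; expected tree frozen from an independent Ward.D oracle."""
    import pandas as pd
    x = np.array([[0.10, 0.20, 0.90],
                  [0.15, 0.25, 0.85],
                  [0.80, 0.75, 0.10],
                  [0.85, 0.80, 0.20],
                  [0.40, 0.60, 0.50],
                  [0.50, 0.55, 0.45]])
    return pd.DataFrame(x, columns=["frp", "relative_weight", "relative_righting"],
                        index=[f"m{i + 1}" for i in range(6)])
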