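import numpy as np
import pandas as pd
import pytest

from delaycorrect import TruncatedDelaySample, fit_retro_hazard


@pytest.fixture
def three_point_sample():
    """Worked 3-unit sample: t=(1,2,3), tau=(2,3,3).

    Hand evaluation: rho = (1, 1/2, 1/2); F = (0, 1/4, 1/2, 1);
    Greenwood var at t=2 is 1/8; weight variance at t=2 is 2.
    """
    return TruncatedDelaySample(t=[1, 2, 3], tau=[2, 3, 3])


@pytest.fixture
def three_point_fit(three_point_sample):
    return fit_retro_hazard(three_point_sample)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def registry_csv(tmp_path):
    """Factory writing a registry CSV from a list of row dicts."""

    def _write(rows, name="registry.csv", columns=None):
        path = tmp_path / name
        df = pd.DataFrame(rows)
        if columns is not None:
            df = df[list(columns)]
        df.to_csv(path, index=False)
        return path

    return _write
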