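import numpy as np
import pytest

from sksformer import synthgen
from sksformer.model import ModelConfig
from sksformer.preprocess import windows_from_series, windows_to_arrays


@pytest.fixture(scope="session")
def gen_config():
    return synthgen.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(gen_config):
    """Default synthetic benchmark: raw windows (filtered + unfiltered)."""
    sessions, manifest = synthgen.generate_dataset(gen_config)
    w_filt = windows_from_series(sessions, filter_enabled=True)
    w_raw = windows_from_series(sessions, filter_enabled=False)
    x_f, y, label_map = windows_to_arrays(w_filt)
    x_r, y_r, _ = windows_to_arrays(w_raw, label_map)
    assert np.array_equal(y, y_r)
    return {"sessions": sessions, "manifest": manifest,
            "X_filtered": x_f, "X_raw": x_r, "y": y, "label_map": label_map}


@pytest.fixture(scope="session")
def reduced_model_config():
    """CPU-scale benchmark architecture (latent width 32)."""
    return ModelConfig(T=200, D=3, K=6, d_model=32, h=4, d_ff=64,
                       c_attn=8, d_s=8, seed=1)


@pytest.fixture
def tiny_model_config():
    """Small shapes for oracle comparisons and property checks."""
    return ModelConfig(T=8, D=3, K=3, d_model=8, h=2, d_ff=16, c_attn=4,
                       d_s=4, kernel_set=(1, 3), conv_groups=2,
                       dropout=0.0, seed=7)
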