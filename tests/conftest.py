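import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_head_params():
    """Factory for random selective-head parameters at a given size."""
    from mambasr.selective_ssm import DeltaPredictor, SSMHeadParams

    def make(channels, state_size, seed=0, hidden=3):
        r = np.random.default_rng(seed)
        predictor = DeltaPredictor(
            W1=r.normal(0, 0.5, (hidden, channels)),
            b1=r.normal(0, 0.1, hidden),
            w2=r.normal(0, 0.5, hidden),
            b2=float(r.normal()),
        )
        return SSMHeadParams(
            a_raw=r.normal(0, 0.5, state_size),
            B=r.normal(0, 0.5, (state_size, channels)),
            C_out=r.normal(0, 0.5, (state_size, channels)),
            D=r.normal(0, 0.5, channels),
            delta_predictor=predictor,
        )

    return make
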