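import numpy as np
import pytest

from frapdyn.io import FrapTrace
from frapdyn.model import TwoStateParams
from frapdyn.synthetic import AcquisitionProtocol, NoiseModel, simulate_frap_trace


@pytest.fixture
def reference_params() -> TwoStateParams:
    """The worked-example parameter set used throughout the tests."""
    return TwoStateParams(f_eq=0.3, c1_eq=0.4, c2_eq=0.25, tau1_eff=2.0, k2_off=0.05)


@pytest.fixture
def noiseless_curve(reference_params):
    trace = simulate_frap_trace(
        reference_params, AcquisitionProtocol(), NoiseModel(sigma_add=0.0, cell_cv=0.0)
    )
    from frapdyn.io import normalize_full_scale

    return normalize_full_scale(trace)


def make_trace(pre_values, post_values, bg=0.0, interval=0.5, cell_id="c1"):
    """Hand-rolled trace builder: pre-bleach frames at t<0, post at t>=0."""
    pre_values = np.asarray(pre_values, dtype=float)
    post_values = np.asarray(post_values, dtype=float)
    n_pre, n_post = len(pre_values), len(post_values)
    time = np.concatenate([
        -np.arange(n_pre, 0, -1) * interval,
        np.arange(n_post) * interval,
    ])
    roi = np.concatenate([pre_values, post_values])
    return FrapTrace(
        cell_id=cell_id,
        time_s=time,
        roi_intensity=roi,
        bg_intensity=np.full(len(time), float(bg)),
    )
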