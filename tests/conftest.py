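import numpy as np
import pytest

from semqc.histogram_metrics import IntensityHistogram, _f_two_gauss


TRUE_PARAMS = dict(amp_m=500.0, mean_m=80.0, var_m=100.0, amp_b=2000.0, mean_b=180.0, var_b=144.0)


def mixture_counts(levels, params, rng=None):
    """Counts from the two-Gaussian model, optionally Poisson-sampled."""
    expected = _f_two_gauss(
        levels,
        params["amp_m"], params["mean_m"], np.sqrt(params["var_m"]),
        params["amp_b"], params["mean_b"], np.sqrt(params["var_b"]),
    )
    if rng is None:
        return np.round(expected).astype(int)
    return rng.poisson(expected)


@pytest.fixture
def bimodal_hist():
    """Noiseless 8-bit two-Gaussian histogram with known parameters."""
    levels = np.arange(256)
    return IntensityHistogram(levels, mixture_counts(levels, TRUE_PARAMS)), TRUE_PARAMS
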