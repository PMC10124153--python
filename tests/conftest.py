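import numpy as np
import pytest

from pharmaqeeg import GroundTruth

#: seven oscillatory bumps with centers inside the vehicle-condition bands
#: (delta through HFO) and widths in the identifiable range
PEAKS7 = (
    (2.0, 3.0, 1.0),
    (3.0, 7.0, 1.5),
    (2.0, 14.0, 2.5),
    (1.5, 30.0, 3.0),
    (1.5, 55.0, 4.0),
    (1.2, 90.0, 5.0),
    (1.2, 150.0, 6.0),
)

#: study-condition Lorentzian background
APERIODIC = {"b": 5.0, "X": 1.5, "k": 0.05}

#: per-bin spectral noise under study conditions, dB
NOISE_SD = 0.2


@pytest.fixture
def lorentzian_truth():
    return GroundTruth(family="lorentzian", aperiodic=dict(APERIODIC))


@pytest.fixture
def seven_peak_truth():
    return GroundTruth(
        family="lorentzian", aperiodic=dict(APERIODIC), peaks=PEAKS7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
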