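import numpy as np
import pytest

from crossfeed import EcologyParams


@pytest.fixture
def paper_params() -> EcologyParams:
    """The measured parameter set: r = 0.02 fmole/cell/h, c = 2 fmole/cell,
    g = dil = ln2/8 per hour, with the default Monod closure."""
    return EcologyParams()


def lstsq_slope(t, y):
    """Independent least-squares slope used by the brute-force window oracles."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    return float(np.polyfit(t, y, 1)[0])
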