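import numpy as np
import pytest

from okrloop.analytics import TimeBin
from okrloop.stimulus import GratingParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bins(specs):
    """specs: list of (tb, tbn, omega, blank, label) tuples."""
    return [
        TimeBin(tb, tbn, GratingParams(omega=om, blank=bl), label=lab)
        for tb, tbn, om, bl, lab in specs
    ]


@pytest.fixture
def alternating_bins():
    """40 s schedule: 4 directed bins alternating CCW/CW, blank head/tail."""
    return make_bins(
        [
            (0.0, 5.0, 30.0, True, "B"),
            (5.0, 12.5, 30.0, False, "d1"),
            (12.5, 20.0, -30.0, False, "d2"),
            (20.0, 27.5, 30.0, False, "d3"),
            (27.5, 35.0, -30.0, False, "d4"),
            (35.0, 40.0, 30.0, True, "B"),
        ]
    )
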