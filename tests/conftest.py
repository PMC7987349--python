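import math
from collections import Counter

import pytest

from tiltscan import AcquisitionConfig, MirrorKinematics, TransducerModel


@pytest.fixture
def kin_ref() -> MirrorKinematics:
    """Reference mirror: 11.95-degree half-range (mean of the measured
    +12.6/-11.3 at 10 Vpp), 250 Hz."""
    return MirrorKinematics(11.95, 250.0)


@pytest.fixture
def tx_ref() -> TransducerModel:
    return TransducerModel()


@pytest.fixture
def acq_ref() -> AcquisitionConfig:
    return AcquisitionConfig()


def brute_force_rate(prfe: float, fm: float, phi: float = 0.0):
    """Independent schedule-enumeration oracle.

    Enumerates sampled tilt phases until the sequence repeats.  If the
    repetition spans one mirror cycle and every non-extremal angle is hit
    exactly twice (each location imaged on the up- and the down-sweep) the
    volume rate is 2*Fm and a volume is one half-sweep inclusive of sampled
    extrema; otherwise the volume is the whole repetition period of m
    cycles and the rate Fm/m.

    Returns (volume_rate, planes_per_volume, regime).
    """
    r = prfe / fm
    period = None
    for n in range(1, 200001):
        if abs(n / r - round(n / r)) < 1e-9 * max(1.0, n / r):
            period = n
            break
    if period is None:
        raise AssertionError("no repetition found")
    vals = [round(math.sin(2 * math.pi * n / r + phi), 9) for n in range(1, period + 1)]
    m = round(period / r)
    if m == 1:
        counts = Counter(vals)
        extremal = [v for v in counts if abs(abs(v) - 1.0) < 1e-9]
        non_ext = {v: c for v, c in counts.items() if v not in extremal}
        if all(c == 2 for c in non_ext.values()) and all(
            counts[v] == 1 for v in extremal
        ):
            n_planes = len(non_ext) + len(extremal)
            return 2.0 * fm, n_planes, "condition1"
    return fm / m, period, "condition2"
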