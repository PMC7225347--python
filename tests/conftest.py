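import numpy as np
import pytest

from aequocal import (
    AequorinParams,
    CalibrationConstants,
    PerfusionProtocol,
    generate_ca_trajectory,
    preset,
)


@pytest.fixture(scope="session")
def protocol():
    return PerfusionProtocol.from_durations()


@pytest.fixture(scope="session")
def constants():
    return CalibrationConstants()


@pytest.fixture(scope="session")
def aequorin():
    return AequorinParams()


@pytest.fixture(scope="session")
def preset_truths():
    """Noise-free ground-truth trajectories for every named preset."""
    out = {}
    for name in (
        "wild_type_biphasic",
        "alpha_syn_monophasic",
        "pmc1_null_fast_only",
        "vcx1_null_biphasic",
    ):
        proto, params = preset(name)
        out[name] = (proto, params, generate_ca_trajectory(proto, params))
    return out
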