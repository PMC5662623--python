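import numpy as np
import pytest

from phlq.model import BoutonTrace, Epoch, KineticParams, Protocol
from phlq.presets import get_preset
from phlq.protocols import get_protocol


@pytest.fixture(scope="session")
def vglut2_params() -> KineticParams:
    return get_preset("VGLUT2").params


@pytest.fixture(scope="session")
def p_10hz60s() -> Protocol:
    return get_protocol("10Hz60s")


@pytest.fixture(scope="session")
def p_rp_baf() -> Protocol:
    return get_protocol("10Hz90s_baf")


def make_trace(
    fluorescence,
    protocol=None,
    frame_interval=3,
    stim=(15.0, 75.0, 10.0),
    baf=False,
    nh4cl=None,
):
    """Build a BoutonTrace around an explicit fluorescence vector."""
    f = np.asarray(fluorescence, dtype=float)
    if protocol is None:
        epochs = [Epoch(*stim[:2], "electrical_stim", stim[2])] if stim else []
        if nh4cl is not None:
            epochs.append(Epoch(*nh4cl, "nh4cl"))
        protocol = Protocol(
            frame_interval,
            len(f),
            tuple(epochs),
            {"bafilomycin": 0.0} if baf else {},
        )
    return BoutonTrace(protocol.times(), f, protocol)
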