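"""Built-in stimulation/bath protocol library.

Names follow the field's shorthand: frequency x duration, with ``_baf`` for
alkaline-trapping runs.  Every protocol ends with an NH4Cl epoch (total-pool
readout) unless noted.  Frame intervals match the acquisition settings used
with each stimulus class: 3 s for 10/40 Hz trains, 6 s for the prolonged
5 Hz train, 1 s for RRP burst measurements.
"""

from __future__ import annotations

from typing import Callable

from .model import Epoch, Protocol


def _train(
    name: str,
    dt: float,
    freq: float,
    stim_s: float,
    recovery_s: float,
    baf: bool,
    nh4cl_s: float = None,
) -> Protocol:
    if nh4cl_s is None:
        nh4cl_s = 5 * dt
    rest = 5 * dt
    stim_start = rest
    stim_end = rest + stim_s
    nh4_start = stim_end + recovery_s
    total = nh4_start + nh4cl_s
    n = int(round(total / dt)) + 1
    epochs = [
        Epoch(stim_start, stim_end, "electrical_stim", freq),
        Epoch(nh4_start, total, "nh4cl"),
    ]
    baths = {"bafilomycin": 0.0} if baf else {}
    return Protocol(dt, n, tuple(epochs), baths, name=name)


def p_10hz60s(recovery_s: float = 240.0) -> Protocol:
    """10 Hz 60 s field stimulation, 3 s frames; endocytosis protocol."""
    return _train("10Hz60s", 3, 10.0, 60.0, recovery_s, baf=False)


def p_10hz90s_baf(recovery_s: float = 30.0) -> Protocol:
    """900 AP at 10 Hz under bafilomycin; RP / exocytosis-rate protocol."""
    return _train("10Hz90s_baf", 3, 10.0, 90.0, recovery_s, baf=True)


def p_5hz300s(recovery_s: float = 300.0) -> Protocol:
    """Prolonged 1500 AP at 5 Hz, 6 s frames."""
    return _train("5Hz300s", 6, 5.0, 300.0, recovery_s, baf=False)


def p_40hz60s(recovery_s: float = 300.0) -> Protocol:
    """High-frequency 2400 AP at 40 Hz, 3 s frames."""
    return _train("40Hz60s", 3, 40.0, 60.0, recovery_s, baf=False)


def p_100hz02s_baf(recovery_s: float = 9.8) -> Protocol:
    """20 AP at 100 Hz under bafilomycin, 1 s frames; RRP burst protocol."""
    return _train("100Hz0.2s_baf", 1, 100.0, 0.2, recovery_s, baf=True)


def p_30hz3s_baf(recovery_s: float = 10.0) -> Protocol:
    """90 AP at 30 Hz under bafilomycin, 1 s frames; alternate RRP protocol."""
    return _train("30Hz3s_baf", 1, 30.0, 3.0, recovery_s, baf=True)


def p_sucrose_baf(recovery_s: float = 10.0) -> Protocol:
    """6 s hypertonic sucrose challenge under bafilomycin, 1 s frames."""
    dt = 1
    rest = 5 * dt
    stim_end = rest + 6.0
    nh4_start = stim_end + recovery_s
    total = nh4_start + 5 * dt
    n = int(round(total / dt)) + 1
    return Protocol(
        dt,
        n,
        (Epoch(rest, stim_end, "sucrose"), Epoch(nh4_start, total, "nh4cl")),
        {"bafilomycin": 0.0},
        name="sucrose_baf",
    )


def p_surface_assay() -> Protocol:
    """pH 5.5 quench -> pH 7.4 rest -> NH4Cl; surface-fraction assay."""
    dt = 3
    return Protocol(
        dt,
        15,
        (Epoch(0.0, 12.0, "ph55_quench"), Epoch(30.0, 42.0, "nh4cl")),
        {},
        name="surface_assay",
    )


def p_fm464_unload(recovery_s: float = 60.0) -> Protocol:
    """FM4-64 destaining at 10 Hz for 90 s; no NH4Cl (dye, not pHluorin)."""
    dt = 3
    rest = 5 * dt
    stim_end = rest + 90.0
    total = stim_end + recovery_s
    n = int(round(total / dt)) + 1
    return Protocol(dt, n, (Epoch(rest, stim_end, "fm_unload"),), {}, name="fm464_unload")


_REGISTRY: dict[str, Callable[..., Protocol]] = {
    "10Hz60s": p_10hz60s,
    "10Hz90s_baf": p_10hz90s_baf,
    "5Hz300s": p_5hz300s,
    "40Hz60s": p_40hz60s,
    "100Hz0.2s_baf": p_100hz02s_baf,
    "30Hz3s_baf": p_30hz3s_baf,
    "sucrose_baf": p_sucrose_baf,
    "surface_assay": p_surface_assay,
    "fm464_unload": p_fm464_unload,
}


def protocol_names() -> list[str]:
    return sorted(_REGISTRY)


def get_protocol(name: str, **kwargs) -> Protocol:
    """Look up a built-in protocol; keyword arguments reach the builder
    (e.g. ``recovery_s`` to extend post-stimulus acquisition)."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {', '.join(protocol_names())}"
        ) from None
    return builder(**kwargs)
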