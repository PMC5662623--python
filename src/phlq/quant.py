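"""Per-bouton quantification of pHluorin traces.

Implements the standard readouts of a synaptic-vesicle recycling experiment:
dF/F0 normalization, single-exponential endocytosis fits, linear and
saturating-exponential exocytosis fits under alkaline trapping, recycling- and
readily-releasable-pool fractions, surface fraction from sequential pH
manipulation, and decay-from-peak during stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import BURST_FREQ_HZ, BoutonTrace, Epoch, Protocol, epoch_mean

POST_STIM_SKIP_S = 3.0
"""Frames earlier than stim_end + 3 s are excluded from the endocytosis fit."""

LINEAR_WINDOW_S = 15.0
"""The linear exocytosis rate is a least-squares slope over the first 15 s."""


class QuantError(ValueError):
    """A quantification precondition is violated."""


@dataclass
class FitResult:
    """Diagnostics of a nonlinear trace fit."""

    tau: float
    amplitude: float
    offset: float
    sse: float
    n_points: int
    converged: bool
    flag: str = "ok"  # ok | non_decaying | wide


@dataclass
class QuantResult:
    """All derived per-bouton quantities; inapplicable fields stay None."""

    bouton_id: int = 0
    coverslip_id: int = 0
    genotype: str = ""
    f0: Optional[float] = None
    total_pool_raw: Optional[float] = None
    total_pool_net: Optional[float] = None
    tau_decay: Optional[float] = None
    tau_exo: Optional[float] = None
    exo_rate_linear: Optional[float] = None
    rp_frac: Optional[float] = None
    rrp_frac: Optional[float] = None
    surface_frac: Optional[float] = None
    decay_from_peak_pct: Optional[float] = None
    time_to_peak: Optional[float] = None
    peak_dff: Optional[float] = None
    dff: Optional[np.ndarray] = field(default=None, repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_row(self) -> dict:
        """Scalar fields as a flat dict (absent values -> None)."""
        out = {}
        for f in fields(self):
            if f.name in ("dff", "diagnostics"):
                continue
            out[f.name] = getattr(self, f.name)
        return out


# ---------------------------------------------------------------------------
# basic trace arithmetic

def subtract_background(
    trace: BoutonTrace,
    background_traces: Sequence[BoutonTrace],
    clip: bool = False,
) -> BoutonTrace:
    """Subtract the frame-wise mean of the background ROIs from ``trace``."""
    if len(background_traces) < 1:
        raise QuantError("at least one background trace is required")
    for bg in background_traces:
        if len(bg) != len(trace) or not np.allclose(bg.time, trace.time):
            raise QuantError("background traces must share the trace's time base")
    bg_mean = np.mean([bg.fluorescence for bg in background_traces], axis=0)
    f = trace.fluorescence - bg_mean
    if clip:
        f = np.clip(f, 0.0, None)
    return BoutonTrace(
        time=trace.time,
        fluorescence=f,
        protocol=trace.protocol,
        bouton_id=trace.bouton_id,
        coverslip_id=trace.coverslip_id,
        genotype=trace.genotype,
    )


def compute_dff(trace: BoutonTrace) -> tuple[float, np.ndarray]:
    """Baseline F0 (mean of the first five frames, pre-stimulus) and dF/F0."""
    if len(trace) < 5:
        raise QuantError("trace shorter than the five baseline frames")
    stim = trace.protocol.stim_epochs()
    if stim and trace.time[4] >= stim[0].start - 1e-9:
        raise QuantError("fewer than five pre-stimulus frames")
    f0 = float(trace.fluorescence[:5].mean())
    if f0 <= 0:
        raise QuantError(f"unusable baseline: F0 = {f0}")
    return f0, (trace.fluorescence - f0) / f0


def normalize(
    dff: np.ndarray,
    mode: str,
    total_pool_net: Optional[float] = None,
    f0: Optional[float] = None,
) -> np.ndarray:
    """Normalize a dF/F0 vector to its peak or to the NH4Cl total pool."""
    dff = np.asarray(dff, dtype=float)
    if mode == "to_peak":
        peak = float(np.max(dff))
        if peak <= 0:
            raise QuantError("peak must be > 0 for to_peak normalization")
        return dff / peak
    if mode == "to_total":
        if total_pool_net is None or total_pool_net <= 0:
            raise QuantError("total_pool_net must be > 0 for to_total normalization")
        if f0 is None or f0 <= 0:
            raise QuantError("f0 must be > 0 for to_total normalization")
        return dff * f0 / total_pool_net
    raise QuantError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# protocol helpers

def _electrical_epoch(protocol: Protocol) -> Epoch:
    eps = [e for e in protocol.stim_epochs() if e.kind == "electrical_stim"]
    if not eps:
        raise QuantError("protocol has no electrical stimulation epoch")
    return eps[0]


def _require_baf(protocol: Protocol) -> None:
    if "bafilomycin" not in protocol.baths:
        raise QuantError("operation requires a bafilomycin (alkaline-trapping) protocol")


def _nh4cl_mean(trace: BoutonTrace) -> float:
    eps = trace.protocol.epochs_of("nh4cl")
    if not eps:
        raise QuantError("protocol has no NH4Cl epoch")
    return epoch_mean(trace, eps[-1])


def total_pool(trace: BoutonTrace) -> tuple[float, float]:
    """(raw, net) total pool: NH4Cl-epoch fluorescence, and minus baseline."""
    f0, _ = compute_dff(trace)
    raw = _nh4cl_mean(trace)
    return raw, raw - f0


# ---------------------------------------------------------------------------
# kinetic fits

def _fit_exponential_decay(t: np.ndarray, y: np.ndarray) -> FitResult:
    """Least-squares fit of y = A exp(-(t - t[0])/tau) + C."""
    tt = t - t[0]
    window = float(tt[-1])
    a0 = max(y[0] - y[-1], 1e-12)
    c0 = min(max(y[-1], 0.0), max(y[0], 1e-12))
    tau0 = max(window / 3.0, 1e-6)
    upper_c = max(float(y[0]), 1e-12)

    def model(x, a, tau, c):
        return a * np.exp(-x / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            tt,
            y,
            p0=[a0, tau0, c0],
            bounds=([0.0, 1e-9, 0.0], [np.inf, 10.0 * window, upper_c]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:  # non-convergence
        resid = np.sum((y - model(tt, a0, tau0, c0)) ** 2)
        raise QuantError(f"exponential fit failed to converge (SSE {resid:.3g})") from exc
    a, tau, c = popt
    sse = float(np.sum((y - model(tt, a, tau, c)) ** 2))
    flag = "wide" if tau > window else "ok"
    return FitResult(float(tau), float(a), float(c), sse, len(y), True, flag)


def fit_endocytosis_tau(
    trace: BoutonTrace, stim_end: Optional[float] = None
) -> FitResult:
    """Single-exponential fit of the post-stimulus fluorescence decay.

    Frames earlier than ``stim_end + 3 s`` and frames inside later bath
    epochs (NH4Cl, pH 5.5) are excluded.  The fit runs on raw fluorescence
    (tau is invariant to the F0 scaling, and the raw baseline keeps the
    offset bound away from the true asymptote under noise).  A non-decaying
    segment (as for endocytosis-dead mutants) yields ``tau = nan`` with flag
    ``non_decaying`` rather than a fit.
    """
    if stim_end is None:
        stim_end = _electrical_epoch(trace.protocol).end
    t = trace.time
    mask = t >= stim_end + POST_STIM_SKIP_S - 1e-9
    for e in trace.protocol.epochs:
        if e.kind in ("nh4cl", "ph55_quench") and e.start > stim_end:
            mask &= t < e.start - 1e-9
    if mask.sum() < 4:
        raise QuantError("need at least 4 frames after stim_end + 3 s for the decay fit")
    tt, yy = t[mask], trace.fluorescence[mask]
    noise_guard = 1e-9 * max(abs(yy[0]), 1.0)
    if yy[0] <= yy[-1] + noise_guard:
        return FitResult(float("nan"), 0.0, float(yy[-1]), 0.0, len(yy), False, "non_decaying")
    return _fit_exponential_decay(tt, yy)


def fit_exocytosis_linear(
    trace: BoutonTrace, stim_start: Optional[float] = None
) -> float:
    """OLS slope of dF/F0 over the first 15 s of stimulation (alkaline trap)."""
    _require_baf(trace.protocol)
    if stim_start is None:
        stim_start = _electrical_epoch(trace.protocol).start
    f0, dff = compute_dff(trace)
    t = trace.time
    mask = (t >= stim_start - 1e-9) & (t <= stim_start + LINEAR_WINDOW_S + 1e-9)
    if mask.sum() < 2 or t[mask][-1] < stim_start + LINEAR_WINDOW_S - trace.protocol.frame_interval:
        raise QuantError("frames do not cover the initial 15 s of stimulation")
    slope = float(np.polyfit(t[mask], dff[mask], 1)[0])
    return slope


def fit_exocytosis_tau(
    trace: BoutonTrace, stim_start: Optional[float] = None
) -> FitResult:
    """Fit dF/F0 during stimulation with B(1 - exp(-(t - t0)/tau))."""
    _require_baf(trace.protocol)
    epoch = _electrical_epoch(trace.protocol)
    if stim_start is None:
        stim_start = epoch.start
    f0, dff = compute_dff(trace)
    t = trace.time
    mask = (t >= stim_start - 1e-9) & (t <= epoch.end + 1e-9)
    if mask.sum() < 4:
        raise QuantError("need at least 4 during-stimulation frames")
    tt = t[mask] - stim_start
    yy = dff[mask]
    window = float(tt[-1])
    b0 = max(float(yy[-1]), 1e-12)

    def model(x, b, tau):
        return b * (1.0 - np.exp(-x / tau))

    try:
        popt, _ = curve_fit(
            model,
            tt,
            yy,
            p0=[b0, max(window / 3.0, 1e-6)],
            bounds=([0.0, 1e-9], [np.inf, 10.0 * window]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise QuantError("saturating-exponential fit failed to converge") from exc
    b, tau = popt
    sse = float(np.sum((yy - model(tt, b, tau)) ** 2))
    flag = "wide" if tau > window else "ok"
    return FitResult(float(tau), float(b), 0.0, sse, len(yy), True, flag)


def ensemble_mean_trace(traces: Sequence[BoutonTrace]) -> BoutonTrace:
    """Frame-wise mean fluorescence across boutons sharing one protocol."""
    if not traces:
        raise QuantError("no traces to average")
    proto = traces[0].protocol
    for tr in traces[1:]:
        if len(tr) != len(traces[0]):
            raise QuantError("traces must share a time base to be averaged")
    mean_f = np.mean([tr.fluorescence for tr in traces], axis=0)
    return BoutonTrace(traces[0].time, mean_f, proto, genotype=traces[0].genotype)


def ensemble_tau_decay(
    traces: Sequence[BoutonTrace],
    mode: str = "per_bouton",
    stim_end: Optional[float] = None,
) -> float:
    """Ensemble endocytosis time constant.

    ``per_bouton`` fits each bouton and averages the finite taus (the
    default, matching per-bouton analysis); ``ensemble_mean`` fits the
    frame-averaged trace, which is far more robust when per-bouton noise is
    comparable to the decay amplitude.
    """
    if mode == "ensemble_mean":
        return fit_endocytosis_tau(ensemble_mean_trace(traces), stim_end).tau
    if mode != "per_bouton":
        raise QuantError(f"unknown fit mode {mode!r}")
    taus = []
    for tr in traces:
        try:
            fit = fit_endocytosis_tau(tr, stim_end)
        except QuantError:
            continue
        if np.isfinite(fit.tau):
            taus.append(fit.tau)
    if not taus:
        raise QuantError("no bouton yielded a finite decay fit")
    return float(np.mean(taus))


# ---------------------------------------------------------------------------
# pool fractions

def compute_rp_fraction(trace: BoutonTrace) -> float:
    """Recycling pool: end-of-stimulation plateau over NH4Cl-minus-baseline.

    The plateau is read as the mean of the last three stimulation frames.
    """
    _require_baf(trace.protocol)
    epoch = _electrical_epoch(trace.protocol)
    f0, _ = compute_dff(trace)
    _, net = total_pool(trace)
    if net <= 0:
        raise QuantError("non-positive total pool")
    idx = trace.protocol.frame_indices(epoch)
    if idx.size < 3:
        return float((trace.fluorescence[idx[-1]] - f0) / net) if idx.size else 0.0
    plateau = float(trace.fluorescence[idx[-3:]].mean()) - f0
    return plateau / net


def compute_rrp_fraction(trace: BoutonTrace, estimator: str) -> float:
    """Readily releasable pool fraction by one of the three estimators.

    burst20AP  mean dF of the first five frames after a >=30 Hz burst / net
    sucrose    mean dF of the first five frames after the sucrose epoch / net
    first30AP  dF at the first frame 1 s after onset of a 30 Hz train / net
    """
    _require_baf(trace.protocol)
    proto = trace.protocol
    f0, _ = compute_dff(trace)
    _, net = total_pool(trace)
    if net <= 0:
        raise QuantError("non-positive total pool")
    t = trace.time

    if estimator in ("burst20AP", "first30AP"):
        if proto.frame_interval != 1:
            raise QuantError(f"{estimator} requires 1 s frame interval")
        epoch = _electrical_epoch(proto)
        if (epoch.frequency_hz or 0) < BURST_FREQ_HZ:
            raise QuantError(f"{estimator} requires a >= 30 Hz burst protocol")
        if estimator == "burst20AP":
            if epoch.duration > 1.5:
                raise QuantError("burst20AP expects a sub-second burst train")
            idx = np.nonzero(t > epoch.end + 1e-9)[0][:5]
            if idx.size < 5:
                raise QuantError("need five post-stimulus frames")
            return float((trace.fluorescence[idx].mean() - f0) / net)
        if epoch.duration < 2.0:
            raise QuantError("first30AP expects a train lasting >= 2 s")
        idx = np.nonzero(t >= epoch.start + 1.0 - 1e-9)[0]
        if idx.size == 0:
            raise QuantError("no frame 1 s after stimulus onset")
        return float((trace.fluorescence[idx[0]] - f0) / net)

    if estimator == "sucrose":
        eps = proto.epochs_of("sucrose")
        if not eps:
            raise QuantError("sucrose estimator requires a sucrose epoch")
        idx = np.nonzero(t > eps[0].end + 1e-9)[0][:5]
        if idx.size < 5:
            raise QuantError("need five post-stimulus frames")
        return float((trace.fluorescence[idx].mean() - f0) / net)

    raise QuantError(f"unknown RRP estimator {estimator!r}")


def compute_surface_fraction(
    f_ph55: float, f_ph74: float, f_nh4cl: float
) -> float:
    """Surface fraction: (F_pH7.4 - F_pH5.5) / F_NH4Cl, clamped at 0."""
    if f_nh4cl <= 0:
        raise QuantError("NH4Cl fluorescence must be > 0")
    frac = (f_ph74 - f_ph55) / f_nh4cl
    if frac < 0:
        warnings.warn("negative surface fraction clamped to 0", stacklevel=2)
        return 0.0
    if frac > 1:
        raise QuantError(f"surface fraction {frac:.3f} exceeds 1")
    return float(frac)


def surface_fraction_from_trace(trace: BoutonTrace) -> float:
    """Apply the sequential pH-manipulation formula to a surface-assay trace."""
    proto = trace.protocol
    ph55 = proto.epochs_of("ph55_quench")
    nh4 = proto.epochs_of("nh4cl")
    if not ph55 or not nh4:
        raise QuantError("surface assay requires pH 5.5 and NH4Cl epochs")
    f_55 = epoch_mean(trace, ph55[0])
    f_nh4 = epoch_mean(trace, nh4[-1])
    t = trace.time
    free = np.ones(len(t), dtype=bool)
    for e in proto.epochs:
        idx = proto.frame_indices(e)
        free[idx] = False
    idx74 = np.nonzero(free & (t > ph55[0].end))[0][:5]
    if idx74.size < 5:
        raise QuantError("need five pH 7.4 frames between quench and NH4Cl")
    f_74 = float(trace.fluorescence[idx74].mean())
    return compute_surface_fraction(f_55, f_74, f_nh4)


def compute_decay_from_peak(
    dff: np.ndarray,
    times: np.ndarray,
    stim_start: float,
    stim_end: float,
) -> tuple[float, float]:
    """Percent decline from peak to the last stimulation frame, and
    time-to-peak (s from stimulus onset; raw frames, earliest tie wins)."""
    dff = np.asarray(dff, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = (times >= stim_start - 1e-9) & (times <= stim_end + 1e-9)
    if not mask.any():
        raise QuantError("no frames within the stimulation window")
    end_idx = np.nonzero(times <= stim_end + 1e-9)[0]
    if times[end_idx[-1]] < stim_end - 1e-9:
        raise QuantError("frames do not cover the end of stimulation")
    sub = dff[mask]
    tsub = times[mask]
    peak_i = int(np.argmax(sub))  # argmax returns the earliest maximum
    peak = float(sub[peak_i])
    if peak <= 0:
        raise QuantError("non-positive peak")
    end_val = float(sub[-1])
    pct = 100.0 * (peak - end_val) / peak
    return pct, float(tsub[peak_i] - stim_start)


# ---------------------------------------------------------------------------
# dispatcher

def quantify(trace: BoutonTrace) -> QuantResult:
    """Populate every quantity computable under the trace's protocol."""
    proto = trace.protocol
    res = QuantResult(
        bouton_id=trace.bouton_id,
        coverslip_id=trace.coverslip_id,
        genotype=trace.genotype,
    )
    has_fm = bool(proto.epochs_of("fm_unload"))
    has_ph55 = bool(proto.epochs_of("ph55_quench"))
    has_nh4 = bool(proto.epochs_of("nh4cl"))
    electrical = [e for e in proto.stim_epochs() if e.kind == "electrical_stim"]
    sucrose = proto.epochs_of("sucrose")
    baf = "bafilomycin" in proto.baths

    if has_ph55 and not electrical and not sucrose:
        if not has_nh4:
            raise QuantError("unrecognized protocol: pH 5.5 quench without NH4Cl")
        res.surface_frac = surface_fraction_from_trace(trace)
        return res

    if not (has_fm or electrical or sucrose):
        raise QuantError("unrecognized protocol: no stimulation or assay epochs")

    f0, dff = compute_dff(trace)
    res.f0 = f0
    res.dff = dff
    if has_fm:
        return res
    if has_nh4:
        res.total_pool_raw, res.total_pool_net = total_pool(trace)

    if electrical:
        epoch = electrical[0]
        if baf:
            if has_nh4 and epoch.duration >= 30.0:
                res.rp_frac = compute_rp_fraction(trace)
            if epoch.duration >= LINEAR_WINDOW_S:
                try:
                    res.exo_rate_linear = fit_exocytosis_linear(trace, epoch.start)
                except QuantError:
                    pass
            if epoch.duration >= 30.0:
                fit = fit_exocytosis_tau(trace, epoch.start)
                res.tau_exo = fit.tau
                res.diagnostics["exo_fit"] = fit
            if has_nh4 and proto.frame_interval == 1 and (epoch.frequency_hz or 0) >= BURST_FREQ_HZ:
                est = "burst20AP" if epoch.duration <= 1.5 else "first30AP"
                res.rrp_frac = compute_rrp_fraction(trace, est)
        else:
            pct, ttp = compute_decay_from_peak(dff, trace.time, epoch.start, epoch.end)
            res.decay_from_peak_pct = pct
            res.time_to_peak = ttp
            stim_mask = (trace.time >= epoch.start - 1e-9) & (trace.time <= epoch.end + 1e-9)
            res.peak_dff = float(np.max(dff[stim_mask]))
            fit = fit_endocytosis_tau(trace, epoch.end)
            res.tau_decay = fit.tau
            res.diagnostics["endo_fit"] = fit
    elif sucrose and baf and has_nh4:
        res.rrp_frac = compute_rrp_fraction(trace, "sucrose")
    return res


def quantify_ensemble(traces: Sequence[BoutonTrace]):
    """Quantify a collection of traces into a tidy per-bouton DataFrame."""
    import pandas as pd

    rows, failures = [], []
    for tr in traces:
        try:
            rows.append(quantify(tr).to_row())
        except QuantError as exc:
            failures.append(
                {"bouton_id": tr.bouton_id, "coverslip_id": tr.coverslip_id, "reason": str(exc)}
            )
    if not rows:
        raise QuantError("all boutons failed quantification")
    return pd.DataFrame(rows), failures
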