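"""Core domain types for pHluorin vesicle-recycling experiments.

A bouton is modelled as a fixed mass of pHluorin-tagged transporter
distributed over compartments that differ only in luminal pH: the quenched
vesicular pool (pH ~5.5), the plasma-membrane surface pool (at bath pH),
and — when the v-ATPase is blocked with bafilomycin — an internalized but
still-alkaline ("trapped") pool at pH 7.4.  Fluorescence is the
brightness-weighted sum over compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

PKA_PHLUORIN = 7.1
"""Apparent pKa of super-ecliptic pHluorin."""

VESICLE_PH = 5.5
"""Steady-state luminal pH of an acidified synaptic vesicle."""

BATH_PH = 7.4

STIM_KINDS = {"electrical_stim", "sucrose", "fm_unload"}
EPOCH_KINDS = STIM_KINDS | {"rest", "nh4cl", "ph55_quench"}

BURST_FREQ_HZ = 30.0
"""Stimulation frequencies at or above this release the RRP within 1 s."""


def ph_brightness(ph: float, pka: float = PKA_PHLUORIN) -> float:
    """Relative pHluorin brightness at ``ph``, normalized to 1 at pH 7.4.

    The protonation equilibrium gives a sigmoidal titration curve
    f(pH) = 1 / (1 + 10^(pKa - pH)); normalizing by f(7.4) makes the fully
    alkalinized (NH4Cl) readout equal the total transporter pool.
    """
    raw = 1.0 / (1.0 + 10.0 ** (pka - ph))
    ref = 1.0 / (1.0 + 10.0 ** (pka - BATH_PH))
    return raw / ref


#: Residual brightness of the quenched vesicular pool relative to alkalinized.
QUENCHED_BRIGHTNESS = ph_brightness(VESICLE_PH)


class ProtocolError(ValueError):
    """A protocol violates one of its structural invariants."""


class ParameterError(ValueError):
    """A kinetic parameter set violates one of its invariants."""


@dataclass(frozen=True)
class Epoch:
    """One timed condition in a protocol.

    ``start``/``end`` are in seconds; membership of a frame is inclusive of
    both endpoints.  ``frequency_hz`` is meaningful for electrical
    stimulation only.
    """

    start: float
    end: float
    kind: str
    frequency_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ProtocolError(f"unknown epoch kind {self.kind!r}")
        if not (self.end > self.start >= 0):
            raise ProtocolError(
                f"epoch must satisfy 0 <= start < end, got [{self.start}, {self.end}]"
            )
        if self.kind == "electrical_stim" and not self.frequency_hz:
            raise ProtocolError("electrical_stim epochs require frequency_hz")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start - 1e-9 <= t <= self.end + 1e-9


@dataclass(frozen=True)
class Protocol:
    """A timed schedule of stimulation epochs and bath conditions.

    ``baths`` maps a global bath flag (``bafilomycin``, ``bfa``) to its onset
    time in seconds.  Frames lie at ``i * frame_interval`` for
    ``i = 0 .. n_frames-1``; any frame not inside an epoch is plain Tyrode's
    at pH 7.4.
    """

    frame_interval: float
    n_frames: int
    epochs: tuple[Epoch, ...] = ()
    baths: dict[str, float] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.frame_interval not in (1, 3, 6):
            raise ProtocolError(
                f"frame_interval must be 1, 3 or 6 s, got {self.frame_interval}"
            )
        if self.n_frames < 1:
            raise ProtocolError("n_frames must be >= 1")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        eps = sorted(self.epochs, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end - 1e-9:
                raise ProtocolError(
                    f"overlapping epochs: [{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        end = self.duration
        for e in eps:
            if e.end > end + 1e-9:
                raise ProtocolError(
                    f"epoch [{e.start},{e.end}] extends past acquisition end {end}"
                )
        stim = self.stim_epochs()
        if stim and stim[0].start < 5 * self.frame_interval - 1e-9:
            raise ProtocolError(
                "five rest frames must precede the first stimulus "
                f"(first stimulus at {stim[0].start} s, need >= {5 * self.frame_interval} s)"
            )
        for key in self.baths:
            if key not in ("bafilomycin", "bfa"):
                raise ProtocolError(f"unknown bath flag {key!r}")

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval)

    def stim_epochs(self) -> list[Epoch]:
        return sorted(
            (e for e in self.epochs if e.kind in STIM_KINDS), key=lambda e: e.start
        )

    def epoch_at(self, t: float) -> Optional[Epoch]:
        for e in self.epochs:
            if e.contains(t):
                return e
        return None

    def epochs_of(self, kind: str) -> list[Epoch]:
        return sorted(
            (e for e in self.epochs if e.kind == kind), key=lambda e: e.start
        )

    def bafilomycin_active(self, t: float) -> bool:
        onset = self.baths.get("bafilomycin")
        return onset is not None and t >= onset - 1e-9

    def frame_indices(self, epoch: Epoch) -> np.ndarray:
        t = self.times()
        return np.nonzero((t >= epoch.start - 1e-9) & (t <= epoch.end + 1e-9))[0]


@dataclass(frozen=True)
class KineticParams:
    """Generative kinetic parameters of one bouton.

    Pool fractions are assay-defined: ``surface_frac`` is what the
    pH 5.5 / pH 7.4 / NH4Cl sequence reads out, and ``rp_frac`` /
    ``rrp_frac`` are fractions of the NH4Cl-minus-baseline total pool, i.e.
    of the internal vesicular pool — the only definitions observable in the
    experiment.

    total_pool      fluorescence of the fully alkalinized transporter (a.u.)
    rp_frac         recycling pool released by 900 AP at 10 Hz, in [0, 1]
    rrp_frac        readily releasable pool, in [0, rp_frac]
    surface_frac    transporter stranded on the plasma membrane at rest
    tau_endo        post-stimulus endocytosis time constant (s)
    tau_exo         exocytosis time constant under alkaline trapping (s)
    exo_rate_linear when set, exocytosis is a constant ramp at this
                    fractional rate (dF/F0 per s) instead of exponential
    noise_sd        additive Gaussian measurement noise (a.u.)
    tau_reacidify   reacidification time constant after endocytosis
                    (s; 0 = instantaneous)
    tau_fm          FM4-64 destaining time constant (s)
    """

    total_pool: float = 1000.0
    rp_frac: float = 0.5
    rrp_frac: float = 0.05
    surface_frac: float = 0.024
    tau_endo: float = 25.0
    tau_exo: float = 25.0
    exo_rate_linear: Optional[float] = None
    noise_sd: float = 0.0
    tau_reacidify: float = 0.0
    tau_fm: float = 30.0

    def __post_init__(self) -> None:
        if self.total_pool <= 0:
            raise ParameterError("total_pool must be > 0")
        for name in ("rp_frac", "rrp_frac", "surface_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.rrp_frac > self.rp_frac + 1e-12:
            raise ParameterError("rrp_frac must not exceed rp_frac")
        if self.tau_endo <= 0 or self.tau_exo <= 0:
            raise ParameterError("tau_endo and tau_exo must be > 0")
        if self.exo_rate_linear is not None and self.exo_rate_linear < 0:
            raise ParameterError("exo_rate_linear must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.tau_reacidify < 0:
            raise ParameterError("tau_reacidify must be >= 0")
        if self.tau_fm <= 0:
            raise ParameterError("tau_fm must be > 0")
        if self.membrane_mass > 1.0:
            raise ParameterError(
                "surface_frac too large for the pH-brightness model "
                f"(implied membrane mass {self.membrane_mass:.3f} > 1)"
            )

    @property
    def membrane_mass(self) -> float:
        """Mass fraction on the plasma membrane implied by ``surface_frac``.

        The assay reads (F_7.4 - F_5.5)/F_NH4Cl = m * (1 - beta) where beta
        is the residual quenched brightness, so m = surface_frac/(1 - beta).
        """
        return self.surface_frac / (1.0 - QUENCHED_BRIGHTNESS)

    @property
    def internal_mass(self) -> float:
        """Mass fraction in acidified vesicles at rest."""
        return 1.0 - self.membrane_mass

    def resting_fluorescence(self) -> float:
        """Baseline F0: quenched vesicular pool plus bright surface pool."""
        m = self.membrane_mass
        return self.total_pool * ((1.0 - m) * QUENCHED_BRIGHTNESS + m)

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass
class BoutonTrace:
    """One ROI's fluorescence time series plus its protocol annotation."""

    time: np.ndarray
    fluorescence: np.ndarray
    protocol: Protocol
    bouton_id: int = 0
    coverslip_id: int = 0
    genotype: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")

    def __len__(self) -> int:
        return len(self.time)


def epoch_mean(trace: BoutonTrace, epoch: Epoch) -> float:
    """Mean fluorescence over the frames falling inside ``epoch``."""
    idx = trace.protocol.frame_indices(epoch)
    if idx.size == 0:
        raise ValueError(f"no frames inside epoch [{epoch.start}, {epoch.end}]")
    return float(trace.fluorescence[idx].mean())
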