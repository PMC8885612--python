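"""Seeded synthetic resuscitation cases with exact ground truth.

Real defibrillator accelerometry shows a strong oscillation at the
compression rate while compressions run, riding on a gravity offset and a
slow baseline drift, with broadband sensor noise throughout; during pauses
the oscillation vanishes up to residual patient/vehicle motion.  The
generator reproduces exactly this phenomenology — the features the
detector actually relies on — from an explicit schedule of compression and
pause segments, so every detected boundary can be scored against a known
truth.  Compression acceleration is modelled as a sinusoid at the
compression rate (110 per minute by default); its 1 s absolute-mean
envelope is then nearly constant and non-vanishing, which is all the
detection chain sees.  Amplitudes switch between segments along smooth
0.3 s half-cosine ramps whose midpoint IS the scheduled boundary, making
the ground-truth boundary well defined to the sample.

Internal acceleration units are arbitrary (the device vendor publishes no
calibration); the default compression amplitude is 1.0 internal unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .io import (
    ARREST,
    CAPNO_FS,
    ROSC_TERMINATION,
    CaseRecord,
    Segmentation,
    UniformTrace,
)

#: 110 compressions per minute, the mid-guideline compression rate.
DEFAULT_CC_RATE_HZ = 110.0 / 60.0


@dataclass(frozen=True)
class SegmentSpec:
    """One schedule entry: a compression bout or a pause."""

    kind: Literal["cc", "pause"]
    duration: float
    #: oscillation frequency, Hz (compression rate, or residual-motion rate)
    cc_rate: float = DEFAULT_CC_RATE_HZ
    #: oscillation amplitude during compressions, internal units
    cc_amplitude: float = 1.0
    #: oscillation amplitude during a pause (residual motion), internal units
    residual_amplitude: float = 0.0

    @property
    def amplitude(self) -> float:
        return self.cc_amplitude if self.kind == "cc" else self.residual_amplitude


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic case."""

    segments: tuple[SegmentSpec, ...]
    noise_sigma: float = 0.02
    #: (gravity offset, drift amplitude, drift frequency Hz); the drift
    #: frequency sits below the detector's 0.2 Hz band edge.
    drift: tuple[float, float, float] = (25.0, 0.5, 0.05)
    fs: float = 250.0
    seed: int = 0
    #: record start in seconds since device power-on
    t_start: float = 300.0
    ramp_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        if any(s.duration <= 0 for s in self.segments):
            raise ValueError("segment durations must be positive")
        max_rate = max(s.cc_rate for s in self.segments)
        if self.fs <= 2 * max_rate:
            raise ValueError("fs must exceed twice the fastest oscillation")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class GroundTruth:
    """The generator's exact compression schedule."""

    periods: Segmentation
    #: expected envelope mean per schedule segment: (kind, 2/pi * amplitude)
    envelope_targets: tuple[tuple[str, float], ...] = ()

    @property
    def boundaries(self) -> np.ndarray:
        return np.sort(np.concatenate([self.periods.starts, self.periods.stops]))


def _half_cosine_kernel(n: int) -> np.ndarray:
    w = np.hanning(n + 2)[1:-1]
    return w / w.sum()


def generate_case(sc: Scenario) -> tuple[CaseRecord, GroundTruth]:
    """Render a :class:`Scenario` into a full case record plus ground truth.

    The accelerometer channel carries the scheduled oscillation with smooth
    amplitude ramps, the gravity offset, the drift sinusoid and Gaussian
    noise, all drawn from the scenario's seed.  ECG and capnography
    channels are simple placeholder waveforms at their nominal rates;
    PhysioStatus marks Arrest at record start and ROSC/Termination at
    record end; the annotation file mirrors the ground truth.
    """
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.total_duration * sc.fs))
    tau = np.arange(n) / sc.fs  # record-local time
    t = sc.t_start + tau

    # piecewise target amplitude / rate from the schedule
    amp = np.empty(n)
    rate = np.empty(n)
    offset = 0.0
    cc_bounds: list[tuple[float, float]] = []
    env_targets: list[tuple[str, float]] = []
    for seg in sc.segments:
        i0 = int(round(offset * sc.fs))
        i1 = min(int(round((offset + seg.duration) * sc.fs)), n)
        amp[i0:i1] = seg.amplitude
        rate[i0:i1] = seg.cc_rate
        if seg.kind == "cc":
            cc_bounds.append((sc.t_start + offset, sc.t_start + offset + seg.duration))
        env_targets.append((seg.kind, 2.0 / np.pi * seg.amplitude))
        offset += seg.duration

    # smooth the amplitude steps with a half-cosine ramp centered on the
    # boundary, so the 50 % point of each transition is the scheduled time
    n_ramp = max(2, int(round(sc.ramp_s * sc.fs)))
    kernel = _half_cosine_kernel(n_ramp)
    pad = len(kernel)
    amp_padded = np.concatenate([np.full(pad, amp[0]), amp, np.full(pad, amp[-1])])
    amp_smooth = np.convolve(amp_padded, kernel, mode="same")[pad:-pad]

    phase = 2 * np.pi * np.cumsum(rate) / sc.fs
    g0, drift_amp, drift_f = sc.drift
    accel_v = (
        amp_smooth * np.sin(phase)
        + g0
        + drift_amp * np.sin(2 * np.pi * drift_f * tau)
        + rng.normal(0.0, sc.noise_sigma, n)
    )
    accel = UniformTrace(t, accel_v, sc.fs)

    # placeholder side channels (shape only, no physiology)
    ecg_v = 0.4 * np.sin(2 * np.pi * 1.1 * tau) + rng.normal(0.0, 0.05, n)
    ecg = UniformTrace(t, ecg_v, sc.fs)
    n_cap = int(round(sc.total_duration * CAPNO_FS))
    tau_cap = np.arange(n_cap) / CAPNO_FS
    capno_v = np.clip(
        38.0 + 4.0 * np.sin(2 * np.pi * 0.25 * tau_cap) + rng.normal(0.0, 0.3, n_cap),
        0.0, None,
    )
    capno = UniformTrace(sc.t_start + tau_cap, capno_v, CAPNO_FS)

    # clip ground-truth boundaries to the record (a schedule may start or
    # end mid-compression on purpose)
    t_end = float(t[-1])
    periods = Segmentation(
        tuple((max(a, float(t[0])), min(b, t_end)) for a, b in cc_bounds)
    )
    truth = GroundTruth(periods=periods, envelope_targets=tuple(env_targets))

    record = CaseRecord(
        accel=accel,
        ecg_pads=ecg,
        capno=capno,
        physio=((ARREST, float(t[0])), (ROSC_TERMINATION, t_end)),
        ann_periods=periods,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _cc(duration: float, **kw) -> SegmentSpec:
    return SegmentSpec("cc", duration, **kw)


def _pause(duration: float, **kw) -> SegmentSpec:
    return SegmentSpec("pause", duration, **kw)


_PRESETS: dict[str, Scenario] = {
    # baseline boundary recovery: well-separated bouts, low noise
    "clean": Scenario(
        segments=(_pause(5), _cc(20), _pause(5), _cc(20), _pause(5)),
        noise_sigma=0.02,
        seed=100,
    ),
    # heavy broadband sensor noise (10 % of the compression amplitude)
    "noisy": Scenario(
        segments=(_pause(5), _cc(20), _pause(5), _cc(20), _pause(5)),
        noise_sigma=0.10,
        seed=101,
    ),
    # residual motion in the gaps: 20 % passes the 35 % envelope-ratio
    # rule, 50 % must be merged away
    "residual_motion": Scenario(
        segments=(
            _pause(4),
            _cc(15),
            _pause(3, residual_amplitude=0.2),
            _cc(15),
            _pause(3, residual_amplitude=0.5),
            _cc(15),
            _pause(4),
        ),
        noise_sigma=0.02,
        seed=102,
    ),
    # 1.0 s gap must be merged (below the 1.6 s floor), 3.0 s gap kept
    "short_pauses": Scenario(
        segments=(_pause(4), _cc(15), _pause(1.0), _cc(15), _pause(3.0), _cc(15), _pause(4)),
        noise_sigma=0.02,
        seed=103,
    ),
    # record begins and ends mid-compression (device switched on late /
    # off early); boundaries must pin to the record edges
    "edge_truncated": Scenario(
        segments=(_cc(12), _pause(4), _cc(12)),
        noise_sigma=0.02,
        seed=104,
    ),
}


def preset(name: str) -> Scenario:
    """A documented fixed scenario exercising one detector behaviour.

    Known names: ``clean``, ``noisy``, ``residual_motion``,
    ``short_pauses``, ``edge_truncated``.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def with_seed(sc: Scenario, seed: int) -> Scenario:
    """The same scenario with a different random seed."""
    return replace(sc, seed=seed)
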