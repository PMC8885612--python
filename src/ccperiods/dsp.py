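"""Signal conditioning for compression detection.

The detector never looks at individual compression cycles.  It works on a
slow summary of the accelerometer channel built in four steps:

1. band-pass filtering (Butterworth, 0.2–50 Hz by default) to strip the
   gravity offset, slow baseline drift and high-frequency noise;
2. a centered sliding mean of the *absolute* filtered acceleration over a
   1 s window — the envelope, which is nearly constant and clearly positive
   while compressions are running and close to zero during pauses;
3. a centered sliding mean (same window) of the envelope's first
   derivative, whose large positive/negative excursions mark compression
   onsets and offsets;
4. soft shrinkage, ``sign(x) * max(|x| - lambda, 0)``, zeroing the small,
   non-significant wiggles of that derivative so that only genuine
   transitions survive as extrema.

All window operations use truncated (renormalized) windows at the record
edges rather than padding, so no data is fabricated where compressions may
already be ongoing when the device is switched on or off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal

from .io import UniformTrace


class DetectorConfig(BaseModel):
    """Every tunable of the detection chain.

    Attributes
    ----------
    band_low, band_high:
        Butterworth band edges in Hz.
    filter_order:
        Butterworth design order per band edge.
    zero_phase:
        Apply the filter forward-backward (no phase delay of the markers);
        ``False`` selects a single causal pass.
    window_s:
        Width in seconds of the centered sliding mean, used both for the
        envelope and for smoothing its derivative.
    pause_ratio:
        A pause is only accepted if its mean absolute acceleration is below
        this fraction of the average of the two flanking compression-period
        means (default 0.35, i.e. the 35 % rule).
    min_pause_s:
        Minimum accepted pause duration in seconds (default 1.6).
    cc_min_level:
        Absolute envelope level (internal units) a compression period must
        reach.  ``None`` resolves it adaptively per record as
        ``cc_min_level_frac`` times the 90th percentile of the envelope
        inside the candidate compression periods.
    shrink_lambda:
        Soft-shrinkage threshold in envelope-derivative units.  ``None``
        resolves it adaptively as ``shrink_frac`` times the 95th percentile
        of the pre-shrinkage ``|d|`` (internal units are device specific, so
        a relative default travels across records).
    refine_window_s:
        Width of the weighted-mean refinement window (default 1 s).
    similar_max_ratio:
        A secondary derivative maximum counts as "similar" (and triggers
        refinement) when its height is at least this fraction of the
        primary maximum.
    refine_starts, refine_stops:
        Which marker kinds the weighted-mean refinement is applied to.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    band_low: float = 0.2
    band_high: float = 50.0
    filter_order: int = 4
    zero_phase: bool = True
    window_s: float = 1.0
    pause_ratio: float = 0.35
    min_pause_s: float = 1.6
    cc_min_level: Optional[float] = None
    cc_min_level_frac: float = 0.20
    shrink_lambda: Optional[float] = None
    shrink_frac: float = 0.10
    refine_window_s: float = 1.0
    similar_max_ratio: float = 0.5
    refine_starts: bool = True
    refine_stops: bool = True

    @model_validator(mode="after")
    def _check(self) -> "DetectorConfig":
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 < self.pause_ratio < 1):
            raise ValueError("pause_ratio must lie in (0, 1)")
        if self.min_pause_s <= 0:
            raise ValueError("min_pause_s must be positive")
        if self.shrink_lambda is not None and self.shrink_lambda < 0:
            raise ValueError("shrink_lambda must be >= 0")
        if self.cc_min_level is not None and self.cc_min_level < 0:
            raise ValueError("cc_min_level must be >= 0")
        if self.refine_window_s <= 0:
            raise ValueError("refine_window_s must be positive")
        if not (0 < self.similar_max_ratio <= 1):
            raise ValueError("similar_max_ratio must lie in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "DetectorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


@dataclass(frozen=True)
class EnvelopeSeries:
    """Centered sliding mean of the absolute filtered acceleration."""

    t: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.e):
            raise ValueError("time base and envelope must have equal length")
        if np.any(self.e < 0):
            raise ValueError("envelope must be non-negative")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DerivSeries:
    """Smoothed (and possibly soft-shrunk) envelope derivative, units/s."""

    t: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.d):
            raise ValueError("time base and derivative must have equal length")

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _window_samples(window_s: float, fs: float) -> int:
    n = int(round(window_s * fs))
    if n < 2:
        raise ValueError("sliding window shorter than 2 samples")
    return n


def _centered_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Centered sliding mean of width ``n``, truncated at the edges."""
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(len(x)), kernel, mode="same")
    return num / den


def bandpass(trace: UniformTrace, cfg: DetectorConfig | None = None) -> UniformTrace:
    """Band-pass a channel with a Butterworth filter.

    Zero-phase (forward-backward) by default, so transition markers derived
    downstream are not delayed against the raw record.  The upper band edge
    must stay below the Nyquist frequency.
    """
    cfg = cfg or DetectorConfig()
    fs = trace.fs_nominal
    if fs <= 2 * cfg.band_high:
        raise ValueError("band edge above Nyquist")
    sos = signal.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high],
        btype="bandpass", fs=fs, output="sos",
    )
    if cfg.zero_phase:
        filtered = signal.sosfiltfilt(sos, trace.v)
    else:
        filtered = signal.sosfilt(sos, trace.v)
    return UniformTrace(trace.t, np.asarray(filtered), trace.fs_nominal)


def sliding_abs_mean(trace: UniformTrace, cfg: DetectorConfig | None = None) -> EnvelopeSeries:
    """Centered sliding mean of ``|v|`` over ``window_s`` (the envelope)."""
    cfg = cfg or DetectorConfig()
    n = _window_samples(cfg.window_s, trace.fs_nominal)
    return EnvelopeSeries(trace.t, _centered_mean(np.abs(trace.v), n))


def smooth_derivative(env: EnvelopeSeries, cfg: DetectorConfig | None = None) -> DerivSeries:
    """Sliding mean (width ``window_s``) of the envelope's first derivative.

    Finite differences are central in the interior and one-sided at the two
    edge samples.
    """
    cfg = cfg or DetectorConfig()
    d = np.gradient(env.e, env.t, edge_order=1)
    n = _window_samples(cfg.window_s, env.fs)
    return DerivSeries(env.t, _centered_mean(d, n))


def soft_shrink(d: DerivSeries, cfg: DetectorConfig | None = None) -> DerivSeries:
    """Soft shrinkage ``sign(x) * max(|x| - lambda, 0)`` of the derivative.

    With ``shrink_lambda=None`` the threshold is ``shrink_frac`` times the
    95th percentile of ``|d|``, a robust ceiling that scales with the
    record's (unknown) internal units.
    """
    cfg = cfg or DetectorConfig()
    lam = resolve_shrink_lambda(d, cfg)
    shrunk = np.sign(d.d) * np.maximum(np.abs(d.d) - lam, 0.0)
    return DerivSeries(d.t, shrunk)


def resolve_shrink_lambda(d: DerivSeries, cfg: DetectorConfig) -> float:
    """The shrinkage threshold actually applied for this series."""
    if cfg.shrink_lambda is not None:
        return cfg.shrink_lambda
    robust_max = float(np.percentile(np.abs(d.d), 95)) if len(d) else 0.0
    return cfg.shrink_frac * robust_max
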