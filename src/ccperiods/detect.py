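"""Chest-compression period detection from the shrunk envelope derivative.

The shrunk derivative is positive where the envelope rises (compressions
starting) and negative where it falls (compressions stopping).  The
detector searches alternately for the absolutely largest extremum of one
kind between extrema of the other kind; those alternating maxima/minima
are the candidate start/stop markers.  Candidates then pass three
acceptance rules, iterated to a fixpoint:

* a pause must last at least ``min_pause_s`` (1.6 s by default);
* the mean envelope inside a pause must stay below ``pause_ratio`` (35 %)
  of the average of the two flanking compression-period means;
* a compression period's mean envelope must not fall below a level
  threshold.

Rejected pauses are merged into their neighbours, rejected compression
periods are absorbed into the surrounding pause, and the rules are
re-applied until nothing changes.  Finally, marker positions are refined:
when the absolute derivative shows a second similarly large maximum close
to a marker, the marker moves to the |d|-weighted mean time over a 1 s
window centered on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.signal import find_peaks

from .dsp import (
    DerivSeries,
    DetectorConfig,
    EnvelopeSeries,
    bandpass,
    sliding_abs_mean,
    smooth_derivative,
    soft_shrink,
)
from .io import Segmentation, UniformTrace

logger = logging.getLogger("ccperiods")

MarkerKind = Literal["start", "stop"]
Verdict = Literal["accepted", "rejected_ratio", "rejected_short"]


@dataclass(frozen=True)
class MarkerCandidate:
    """A candidate period boundary: an extremum of the shrunk derivative."""

    time: float
    kind: MarkerKind
    strength: float  # |d| at the extremum


@dataclass(frozen=True)
class GapRecord:
    """Audit record of one pause tested by the acceptance rules."""

    start: float
    stop: float
    pause_env_mean: float
    flank_env_means: tuple[float, float]
    verdict: Verdict

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def ratio(self) -> float:
        """Pause mean over the average flank mean (the 35 % rule quantity)."""
        flank = 0.5 * (self.flank_env_means[0] + self.flank_env_means[1])
        return self.pause_env_mean / flank if flank > 0 else np.inf


# ---------------------------------------------------------------------------
# Candidate search
# ---------------------------------------------------------------------------

def alternating_extrema(d: DerivSeries) -> list[MarkerCandidate]:
    """Alternating maxima (starts) and minima (stops) of the derivative.

    Each returned extremum is the absolutely largest of its kind between
    its neighbours of the other kind; equal magnitudes resolve to the
    earliest time.  An all-zero derivative yields an empty list.
    """
    sgn = np.sign(d.d)
    # run-wise extrema of each maximal nonzero same-sign run
    extrema: list[tuple[int, float]] = []  # (sample index, signed value)
    i = 0
    n = len(d)
    while i < n:
        s = sgn[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and sgn[j] == s:
            j += 1
        run = d.d[i:j]
        k = i + int(np.argmax(np.abs(run)))  # argmax: earliest on ties
        extrema.append((k, float(d.d[k])))
        i = j
    # merge consecutive same-sign run extrema, keeping the absolutely
    # largest (strictly larger wins, so ties stay with the earliest)
    merged: list[tuple[int, float]] = []
    for k, val in extrema:
        if merged and np.sign(val) == np.sign(merged[-1][1]):
            if abs(val) > abs(merged[-1][1]):
                merged[-1] = (k, val)
        else:
            merged.append((k, val))
    return [
        MarkerCandidate(
            time=float(d.t[k]),
            kind="start" if val > 0 else "stop",
            strength=abs(val),
        )
        for k, val in merged
    ]


# ---------------------------------------------------------------------------
# Acceptance rules
# ---------------------------------------------------------------------------

def _env_mean(env: EnvelopeSeries, a: float, b: float) -> float:
    i0, i1 = np.searchsorted(env.t, [a, b])
    i1 = min(i1 + 1, len(env))  # include the sample at b
    if i1 <= i0:
        return 0.0
    return float(np.mean(env.e[i0:i1]))


def resolve_cc_min_level(
    periods: list[tuple[float, float]], env: EnvelopeSeries, cfg: DetectorConfig
) -> float:
    """Envelope level a compression period must reach.

    Adaptive default: ``cc_min_level_frac`` of the 90th-percentile envelope
    inside the candidate compression periods, so the rule follows the
    record's internal-unit scale.
    """
    if cfg.cc_min_level is not None:
        return cfg.cc_min_level
    samples = []
    for a, b in periods:
        i0, i1 = np.searchsorted(env.t, [a, b])
        samples.append(env.e[i0 : min(i1 + 1, len(env))])
    if not samples:
        return 0.0
    pooled = np.concatenate([s for s in samples if len(s)] or [np.zeros(1)])
    if not len(pooled):
        return 0.0
    return cfg.cc_min_level_frac * float(np.percentile(pooled, 90))


def filter_candidates(
    candidates: list[MarkerCandidate],
    env: EnvelopeSeries,
    cfg: DetectorConfig | None = None,
) -> tuple[Segmentation, list[GapRecord]]:
    """Apply the three acceptance rules to the candidate markers.

    Candidates pair up into compression periods with pauses in between.  A
    record that begins (ends) mid-compression — candidate list starting
    with a stop (ending with a start) — gets a synthetic boundary pinned to
    the record edge.  Pauses failing the duration or ratio rule are merged
    into their neighbours; compression periods below the level threshold
    are absorbed into the surrounding pause; both rules re-run until the
    segmentation stops changing.  Every pause verdict (including the final
    accepted ones) is logged as a :class:`GapRecord`.
    """
    cfg = cfg or DetectorConfig()
    t0, t1 = float(env.t[0]), float(env.t[-1])

    times = [c.time for c in candidates]
    kinds = [c.kind for c in candidates]
    if not candidates:
        # No transitions at all: either compressions run wall-to-wall or
        # the record is silent.  Treat the whole record as one candidate
        # period and let the level rule decide.
        times, kinds = [t0, t1], ["start", "stop"]
    else:
        if kinds[0] == "stop":
            times.insert(0, t0)
            kinds.insert(0, "start")
        if kinds[-1] == "start":
            times.append(t1)
            kinds.append("stop")

    periods = [(times[i], times[i + 1]) for i in range(0, len(times) - 1, 2)]
    periods = [(a, b) for a, b in periods if b > a]
    level = resolve_cc_min_level(periods, env, cfg)

    gaps: list[GapRecord] = []
    changed = True
    while changed:
        changed = False
        # pause rules: duration floor, then envelope-ratio ceiling
        for i in range(len(periods) - 1):
            a, b = periods[i][1], periods[i + 1][0]
            pause_mean = _env_mean(env, a, b)
            flanks = (
                _env_mean(env, *periods[i]),
                _env_mean(env, *periods[i + 1]),
            )
            verdict: Optional[str] = None
            if b - a < cfg.min_pause_s:
                verdict = "rejected_short"
            elif not pause_mean < cfg.pause_ratio * (0.5 * (flanks[0] + flanks[1])):
                verdict = "rejected_ratio"
            if verdict is not None:
                gaps.append(GapRecord(a, b, pause_mean, flanks, verdict))
                logger.debug("pause %.3f-%.3f s %s", a, b, verdict)
                periods[i : i + 2] = [(periods[i][0], periods[i + 1][1])]
                changed = True
                break
        if changed:
            continue
        # level rule on the compression periods themselves
        for i, (a, b) in enumerate(periods):
            m = _env_mean(env, a, b)
            if not (m > 0.0 and m >= level):
                logger.debug("period %.3f-%.3f s below level %.4g, removed", a, b, level)
                del periods[i]
                changed = True
                break

    for i in range(len(periods) - 1):
        a, b = periods[i][1], periods[i + 1][0]
        gaps.append(
            GapRecord(
                a, b, _env_mean(env, a, b),
                (_env_mean(env, *periods[i]), _env_mean(env, *periods[i + 1])),
                "accepted",
            )
        )
    return Segmentation(tuple(periods)), gaps


# ---------------------------------------------------------------------------
# Weighted-mean marker refinement
# ---------------------------------------------------------------------------

def refine_marker(t0: float, d_abs: DerivSeries, cfg: DetectorConfig | None = None) -> float:
    """Refine one marker with a |d|-weighted mean time.

    The oscillatory raw acceleration can split a single envelope transition
    into two nearby derivative maxima.  When a second local maximum of
    ``|d|`` with height at least ``similar_max_ratio`` times the marker's
    own lies inside the ``refine_window_s`` window centered on ``t0``, the
    marker moves to the weighted mean time of that window, the absolute
    derivative acting as the weight; otherwise ``t0`` is returned as is.
    """
    cfg = cfg or DetectorConfig()
    half = 0.5 * cfg.refine_window_s
    t = d_abs.t
    w = np.abs(d_abs.d)
    i0, i1 = np.searchsorted(t, [t0 - half, t0 + half])
    i1 = min(i1 + 1, len(t))
    if i1 - i0 < 3:
        return t0
    tt, ww = t[i0:i1], w[i0:i1]
    k0 = int(np.argmin(np.abs(tt - t0)))
    s0 = float(ww[k0])
    if s0 <= 0:
        return t0
    peaks, _ = find_peaks(ww)
    dt = float(np.median(np.diff(tt)))
    secondary = [
        p for p in peaks
        if abs(tt[p] - tt[k0]) > 1.5 * dt and ww[p] >= cfg.similar_max_ratio * s0
    ]
    if not secondary:
        return t0
    total = float(np.sum(ww))
    if total <= 0:
        return t0
    return float(np.sum(tt * ww) / total)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def detect(
    trace: UniformTrace, cfg: DetectorConfig | None = None
) -> tuple[Segmentation, list[GapRecord]]:
    """Detect chest-compression periods in an accelerometer trace.

    Runs the full chain — band-pass, envelope, smoothed derivative, soft
    shrinkage, alternating-extrema search, the three acceptance rules, and
    weighted-mean refinement — and returns the period segmentation together
    with the audit trail of pause verdicts.  Markers are clipped to the
    record's time range.
    """
    cfg = cfg or DetectorConfig()
    if trace.duration < 2 * cfg.window_s:
        raise ValueError("record too short")
    filtered = bandpass(trace, cfg)
    env = sliding_abs_mean(filtered, cfg)
    der = smooth_derivative(env, cfg)
    shrunk = soft_shrink(der, cfg)
    candidates = alternating_extrema(shrunk)
    seg, gaps = filter_candidates(candidates, env, cfg)

    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    half = 0.5 * cfg.refine_window_s
    refined: list[tuple[float, float]] = []
    for a, b in seg:
        ra, rb = a, b
        # markers pinned to a record edge are synthetic: leave them alone
        if cfg.refine_starts and a - t0 >= half and t1 - a >= half:
            ra = refine_marker(a, shrunk, cfg)
        if cfg.refine_stops and b - t0 >= half and t1 - b >= half:
            rb = refine_marker(b, shrunk, cfg)
        if not ra < rb:  # refinement must never invert a period
            ra, rb = a, b
        refined.append((min(max(ra, t0), t1), min(max(rb, t0), t1)))
    # a refined boundary may not cross into its neighbour period
    for i in range(len(refined) - 1):
        if refined[i][1] > refined[i + 1][0]:
            refined[i] = (refined[i][0], seg.periods[i][1])
            refined[i + 1] = (seg.periods[i + 1][0], refined[i + 1][1])
    return Segmentation(tuple(refined)), gaps
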