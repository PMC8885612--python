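"""Candidate search, acceptance rules, refinement and the full chain."""

import itertools

import numpy as np
import pytest

from ccperiods import (
    DerivSeries,
    DetectorConfig,
    EnvelopeSeries,
    MarkerCandidate,
    Scenario,
    SegmentSpec,
    UniformTrace,
    alternating_extrema,
    detect,
    filter_candidates,
    generate_case,
    refine_marker,
)

FS = 250.0


def series(values, fs=FS):
    values = np.asarray(values, dtype=float)
    return DerivSeries(np.arange(len(values)) / fs, values)


def envelope(values, fs=FS, t0=0.0):
    values = np.asarray(values, dtype=float)
    return EnvelopeSeries(t0 + np.arange(len(values)) / fs, values)


# ---------------------------------------------------------------------------
# Brute-force oracle for the alternating-extrema search
# ---------------------------------------------------------------------------

def oracle_alternating(d: DerivSeries):
    """Exhaustive search over alternating subsequences of run extrema.

    Enumerates the per-run extrema of the derivative, then every maximal
    alternating-sign subsequence, and keeps the one where each element is
    the absolutely largest of its sign strictly between its neighbours of
    the other sign (earliest time on ties).  Independent of the
    implementation's merge strategy.
    """
    sgn = np.sign(d.d)
    runs = []
    i = 0
    while i < len(d):
        if sgn[i] == 0:
            i += 1
            continue
        j = i
        while j < len(d) and sgn[j] == sgn[i]:
            j += 1
        k = min(range(i, j), key=lambda m: (-abs(d.d[m]), m))
        runs.append((k, float(d.d[k])))
        i = j
    if not runs:
        return []
    # group consecutive same-sign runs into blocks; a maximal alternating
    # subsequence picks exactly one run extremum per block
    blocks = []
    for k, val in runs:
        if blocks and np.sign(val) == np.sign(blocks[-1][0][1]):
            blocks[-1].append((k, val))
        else:
            blocks.append([(k, val)])
    best = None
    for choice in itertools.product(*blocks):
        ok = True
        for pos, (k, val) in enumerate(choice):
            lo = choice[pos - 1][0] if pos > 0 else -1
            hi = choice[pos + 1][0] if pos + 1 < len(choice) else len(d)
            for k2, val2 in runs:
                if lo < k2 < hi and np.sign(val2) == np.sign(val):
                    if abs(val2) > abs(val) or (abs(val2) == abs(val) and k2 < k):
                        ok = False
                        break
            if not ok:
                break
        if ok:
            assert best is None, "oracle found two valid alternating sequences"
            best = choice
    assert best is not None, "oracle found no valid alternating sequence"
    return [
        ("start" if val > 0 else "stop", float(d.t[k]), abs(val)) for k, val in best
    ]


def random_shrunk_series(rng, n):
    """A short, plausibly shrunk derivative: smooth noise with a dead zone."""
    raw = np.convolve(rng.standard_normal(n), np.ones(5) / 5, mode="same")
    lam = np.percentile(np.abs(raw), rng.uniform(20, 70))
    return series(np.sign(raw) * np.maximum(np.abs(raw) - lam, 0.0))


class TestAlternatingExtrema:
    def test_zero_derivative_yields_no_candidates(self):
        assert alternating_extrema(series(np.zeros(100))) == []

    def test_single_positive_then_negative_lobe(self):
        d = np.zeros(100)
        d[10:20] = np.sin(np.linspace(0, np.pi, 10))  # peak at index ~14
        d[60:70] = -2 * np.sin(np.linspace(0, np.pi, 10))
        out = alternating_extrema(series(d))
        assert [c.kind for c in out] == ["start", "stop"]
        assert out[0].time == pytest.approx(np.argmax(d) / FS)
        assert out[1].time == pytest.approx(np.argmin(d) / FS)
        assert out[1].strength == pytest.approx(float(np.max(np.abs(d))), rel=1e-9)

    def test_largest_of_two_positive_lobes_wins(self):
        d = np.zeros(200)
        d[10:20] = 1.0
        d[50:60] = 3.0
        d[100:110] = -1.5
        out = alternating_extrema(series(d))
        assert [c.kind for c in out] == ["start", "stop"]
        assert out[0].time == pytest.approx(50 / FS)  # the height-3 lobe
        assert out[0].strength == pytest.approx(3.0)

    def test_kinds_strictly_alternate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = random_shrunk_series(rng, 150)
            kinds = [c.kind for c in alternating_extrema(d)]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            d = random_shrunk_series(rng, int(rng.integers(20, 200)))
            got = [(c.kind, c.time, c.strength) for c in alternating_extrema(d)]
            want = oracle_alternating(d)
            assert got == pytest.approx(want) if got else got == want


# ---------------------------------------------------------------------------
# The three acceptance rules
# ---------------------------------------------------------------------------

def two_period_envelope(gap_s, gap_level, flank_level=1.0, flank_s=10.0, fs=FS):
    """Envelope: flank_s at flank_level, gap, flank_s at flank_level."""
    n_f, n_g = int(flank_s * fs), int(gap_s * fs)
    e = np.concatenate(
        [np.full(n_f, flank_level), np.full(n_g, gap_level), np.full(n_f, flank_level)]
    )
    env = envelope(e, fs)
    t_stop = n_f / fs
    t_start = (n_f + n_g) / fs
    cands = [
        MarkerCandidate(0.5, "start", 1.0),
        MarkerCandidate(t_stop, "stop", 1.0),
        MarkerCandidate(t_start, "start", 1.0),
        MarkerCandidate(env.t[-1] - 0.5, "stop", 1.0),
    ]
    return env, cands


class TestFilterCandidates:
    def test_short_silent_gap_merged(self):
        env, cands = two_period_envelope(gap_s=1.0, gap_level=0.0)
        seg, gaps = filter_candidates(cands, env, DetectorConfig())
        assert len(seg) == 1
        assert any(g.verdict == "rejected_short" for g in gaps)
        assert not any(g.verdict == "accepted" for g in gaps)

    def test_fifty_percent_gap_rejected_by_ratio(self):
        env, cands = two_period_envelope(gap_s=3.0, gap_level=0.5)
        seg, gaps = filter_candidates(cands, env, DetectorConfig())
        assert len(seg) == 1
        assert any(g.verdict == "rejected_ratio" for g in gaps)

    def test_quiet_long_gap_accepted(self):
        env, cands = two_period_envelope(gap_s=3.0, gap_level=0.05)
        seg, gaps = filter_candidates(cands, env, DetectorConfig())
        assert len(seg) == 2
        accepted = [g for g in gaps if g.verdict == "accepted"]
        assert len(accepted) == 1
        assert accepted[0].duration >= 1.6
        assert accepted[0].ratio < 0.35

    def test_low_level_period_between_genuine_pauses_removed(self):
        fs = FS
        # strong period, pause, weak hum "period", pause, strong period
        e = np.concatenate(
            [
                np.full(int(10 * fs), 1.0),
                np.full(int(3 * fs), 0.01),
                np.full(int(4 * fs), 0.05),  # below the adaptive level
                np.full(int(3 * fs), 0.01),
                np.full(int(10 * fs), 1.0),
            ]
        )
        env = envelope(e, fs)
        cands = [
            MarkerCandidate(0.5, "start", 1.0),
            MarkerCandidate(10.0, "stop", 1.0),
            MarkerCandidate(13.0, "start", 0.2),
            MarkerCandidate(17.0, "stop", 0.2),
            MarkerCandidate(20.0, "start", 1.0),
            MarkerCandidate(29.5, "stop", 1.0),
        ]
        seg, _ = filter_candidates(cands, env, DetectorConfig())
        assert len(seg) == 2
        assert all(not (13.5 < a < 16.5) for a, _ in seg)

    def test_record_starting_with_stop_gets_edge_start(self):
        fs = FS
        e = np.concatenate([np.full(int(10 * fs), 1.0), np.full(int(5 * fs), 0.01)])
        env = envelope(e, fs, t0=100.0)
        cands = [MarkerCandidate(110.0, "stop", 1.0)]
        seg, _ = filter_candidates(cands, env, DetectorConfig())
        assert len(seg) == 1
        assert seg.periods[0][0] == pytest.approx(100.0)

    def test_no_candidates_all_quiet_yields_empty(self):
        env = envelope(np.zeros(int(30 * FS)))
        seg, gaps = filter_candidates([], env, DetectorConfig())
        assert len(seg) == 0 and gaps == []


class TestRefineMarker:
    def test_isolated_maximum_unchanged(self):
        d = np.zeros(2000)
        d[1000:1010] = np.sin(np.linspace(0, np.pi, 10))
        t0 = float(np.argmax(d) / FS)
        assert refine_marker(t0, series(d), DetectorConfig()) == t0

    def test_two_equal_maxima_symmetric_weight_gives_midpoint(self):
        d = np.zeros(2000)
        mid = 1000
        off = int(0.2 * FS)
        for c in (mid - off, mid + off):
            d[c - 10 : c + 10] += np.exp(-0.5 * ((np.arange(-10, 10)) / 4) ** 2)
        t0 = mid / FS
        refined = refine_marker(t0, series(d), DetectorConfig())
        assert refined == pytest.approx(t0, abs=1e-6)

    def test_two_unequal_maxima_move_to_weighted_centroid(self):
        d = np.zeros(2000)
        p1, p2 = 1000, 1000 + int(0.3 * FS)
        d[p1 - 8 : p1 + 8] += 1.0
        d[p2 - 8 : p2 + 8] += 0.7
        ds = series(d)
        t0 = p1 / FS
        refined = refine_marker(t0, ds, DetectorConfig())
        # direct summation oracle over the centered window samples
        half = 0.5
        mask = (ds.t >= t0 - half) & (ds.t <= t0 + half)
        oracle = np.sum(ds.t[mask] * np.abs(ds.d[mask])) / np.sum(np.abs(ds.d[mask]))
        assert refined == pytest.approx(oracle, abs=1e-9)
        assert refined > t0  # pulled toward the secondary maximum

    def test_dissimilar_secondary_maximum_ignored(self):
        d = np.zeros(2000)
        p1, p2 = 1000, 1000 + int(0.3 * FS)
        d[p1 - 8 : p1 + 8] += 1.0
        d[p2 - 8 : p2 + 8] += 0.2  # below similar_max_ratio * primary
        t0 = p1 / FS
        assert refine_marker(t0, series(d), DetectorConfig()) == t0


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def cc_pause_cc(gap_s=5.0, seed=7, **kw):
    return Scenario(
        segments=(
            SegmentSpec("cc", 20.0),
            SegmentSpec("pause", gap_s),
            SegmentSpec("cc", 20.0),
        ),
        seed=seed,
        **kw,
    )


class TestDetect:
    def test_all_zero_trace_yields_empty_segmentation(self):
        t = np.arange(int(60 * FS)) / FS
        seg, gaps = detect(UniformTrace(t, np.zeros_like(t), FS))
        assert len(seg) == 0

    def test_uninterrupted_sinusoid_is_one_full_period(self):
        t = np.arange(int(60 * FS)) / FS
        trace = UniformTrace(t, np.sin(2 * np.pi * 2.0 * t), FS)
        seg, _ = detect(trace)
        assert len(seg) == 1
        assert seg.total_time >= 0.95 * (t[-1] - t[0])

    def test_record_too_short_fatal(self):
        t = np.arange(300) / FS  # 1.2 s < 2 * window
        with pytest.raises(ValueError, match="record too short"):
            detect(UniformTrace(t, np.ones(300), FS))

    def test_two_bout_case_boundaries_within_half_second(self):
        record, truth = generate_case(cc_pause_cc())
        seg, _ = detect(record.accel)
        assert len(seg) == 2
        got = np.sort(np.concatenate([seg.starts, seg.stops]))
        np.testing.assert_allclose(got, truth.boundaries, atol=0.5)

    def test_periods_disjoint_and_inside_record(self):
        for name_seed in range(3):
            record, _ = generate_case(cc_pause_cc(seed=50 + name_seed))
            seg, _ = detect(record.accel)
            t0, t1 = record.accel.t[0], record.accel.t[-1]
            prev_stop = t0
            for a, b in seg:
                assert t0 <= a < b <= t1
                assert a >= prev_stop
                prev_stop = b

    def test_reported_pauses_obey_both_rules(self):
        record, _ = generate_case(cc_pause_cc(gap_s=4.0))
        cfg = DetectorConfig()
        _, gaps = detect(record.accel, cfg)
        accepted = [g for g in gaps if g.verdict == "accepted"]
        assert accepted
        for g in accepted:
            assert g.duration >= cfg.min_pause_s
            assert g.ratio < cfg.pause_ratio

    def test_amplitude_equivariance(self):
        record, _ = generate_case(cc_pause_cc(seed=9))
        base, _ = detect(record.accel)
        dt = 1.0 / FS
        for c in (0.01, 100.0):
            scaled = UniformTrace(record.accel.t, c * record.accel.v, FS)
            seg, _ = detect(scaled)
            assert len(seg) == len(base)
            np.testing.assert_allclose(seg.starts, base.starts, atol=dt)
            np.testing.assert_allclose(seg.stops, base.stops, atol=dt)

    def test_time_shift_equivariance(self):
        record, _ = generate_case(cc_pause_cc(seed=13))
        base, _ = detect(record.accel)
        shift = 1234.5
        moved = UniformTrace(record.accel.t + shift, record.accel.v, FS)
        seg, _ = detect(moved)
        np.testing.assert_allclose(seg.starts, base.starts + shift, atol=1e-6)
        np.testing.assert_allclose(seg.stops, base.stops + shift, atol=1e-6)

    def test_lowering_pause_floor_never_loses_pauses(self):
        sc = Scenario(
            segments=(
                SegmentSpec("cc", 12.0),
                SegmentSpec("pause", 1.2),
                SegmentSpec("cc", 12.0),
                SegmentSpec("pause", 2.5),
                SegmentSpec("cc", 12.0),
            ),
            seed=21,
        )
        record, _ = generate_case(sc)
        n_prev = -1
        for floor in (2.0, 1.6, 1.0, 0.5):
            seg, _ = detect(record.accel, DetectorConfig(min_pause_s=floor))
            n_pauses = len(seg) - 1
            assert n_pauses >= n_prev
            n_prev = n_pauses
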