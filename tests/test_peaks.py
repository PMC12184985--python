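"""Paired sparse-enrichment peak calling, checked against a brute-force
oracle that rebuilds blocks base by base and re-derives the threshold by
exhaustive candidate enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cutac.coverage import CoverageTrack
from cutac.peaks import (PeakSet, SignalBlock, call_peaks, select_threshold,
                         signal_blocks, overlap_with_intervals,
                         _control_scale)


def track(values, chrom="chr1", mito="chrM"):
    return CoverageTrack(values={chrom: np.asarray(values, dtype=float)},
                         scale_factor=1.0, mito_name=mito)


def blocks(totals):
    return [SignalBlock("chr1", 10 * i, 10 * i + 1, float(t), float(t))
            for i, t in enumerate(totals)]


# -- independent oracle ---------------------------------------------------


def oracle_blocks(values, chrom="chr1"):
    """Naive base-scan block construction."""
    out, start = [], None
    for i, v in enumerate(list(values) + [0.0]):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            seg = values[start:i]
            out.append(SignalBlock(chrom, start, i, float(np.sum(seg)),
                                   float(np.max(seg))))
            start = None
    return out


def oracle_threshold(t_blocks, c_blocks, mode, min_separation=0.005,
                     normalize=True, tol=0.01):
    """Exhaustive threshold scan with the same selection semantics."""
    t_tot = sorted(b.total_signal for b in t_blocks)
    c_tot = sorted(b.total_signal for b in c_blocks)
    if normalize:
        scale = _control_scale(np.array(t_tot), np.array(c_tot))
        c_tot = [c * scale for c in c_tot]
    cands = sorted(set(t_tot) | set(c_tot))
    if len(cands) == 1:
        return cands[0]
    d = []
    for t in cands:
        f_t = sum(x >= t for x in t_tot) / len(t_tot)
        f_c = sum(x >= t * (1 - tol) for x in c_tot) / len(c_tot)
        d.append(f_t - f_c)
    d_max = max(d)
    if d_max <= min_separation:
        return cands[-1]
    tied = [t for t, v in zip(cands, d) if v >= d_max - 1e-9]
    return max(tied) if mode == "stringent" else min(tied)


def oracle_call(t_values, c_values, mode):
    tb = oracle_blocks(t_values)
    cb = oracle_blocks(c_values)
    if not tb:
        return []
    thr = (oracle_threshold(tb, cb, mode) if cb
           else min(b.total_signal for b in tb))
    return [b for b in tb if b.total_signal >= thr]


# -- unit behavior --------------------------------------------------------


class TestSignalBlocks:
    def test_all_zero_track(self):
        assert signal_blocks(track(np.zeros(50))) == []

    def test_single_block_totals(self):
        v = np.zeros(20)
        v[0:5] = 2.0
        b, = signal_blocks(track(v))
        assert (b.start, b.end) == (0, 5)
        assert b.total_signal == pytest.approx(10.0)
        assert b.max_signal == pytest.approx(2.0)

    def test_single_zero_base_splits_blocks(self):
        v = np.ones(10)
        v[4] = 0.0
        bs = signal_blocks(track(v))
        assert [(b.start, b.end) for b in bs] == [(0, 4), (5, 10)]


class TestSelectThreshold:
    """Toy-list checks of the core scan (no control rescaling)."""

    kw = dict(normalize_control=False, min_separation=0.0)

    def test_clear_separation(self):
        thr = select_threshold(blocks([10, 10, 10]), blocks([1, 1, 1]),
                               "stringent", **self.kw)
        assert 1 < thr <= 10
        assert sum(t >= thr for t in [10, 10, 10]) == 3
        assert sum(t >= thr for t in [1, 1, 1]) == 0

    def test_enumerated_candidates(self):
        # target (5,9), control (1,2): gap maximized at t=5
        thr = select_threshold(blocks([5, 9]), blocks([1, 2]), "stringent",
                               **self.kw)
        assert thr == 5.0

    def test_identical_distributions_pass_at_most_one(self):
        thr = select_threshold(blocks([1, 4, 7]), blocks([1, 4, 7]),
                               "stringent", **self.kw)
        assert thr == 7.0

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            thr = select_threshold(blocks([3, 3]), blocks([3, 3]),
                                   "stringent", **self.kw)
        assert thr == 3.0

    def test_relaxed_picks_smallest_tied_threshold(self):
        # d(t) ties at 2 and 3 (both exclude all controls, keep both targets)
        thr_r = select_threshold(blocks([2, 3]), blocks([1, 1]), "relaxed",
                                 **self.kw)
        thr_s = select_threshold(blocks([2, 3]), blocks([1, 1]), "stringent",
                                 **self.kw)
        assert thr_r == 2.0
        assert thr_s == 2.0  # unique argmax here: t=2 keeps both targets


class TestCallPeaks:
    def test_identical_tracks_give_at_most_one_peak(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(0.5, size=400) * rng.uniform(0.5, 1.5, size=400)
        ps = call_peaks(track(v), track(v.copy()))
        assert len(ps) <= 1

    def test_empty_tumor_warns(self):
        with pytest.warns(UserWarning):
            ps = call_peaks(track(np.zeros(50)), track(np.ones(50)))
        assert len(ps) == 0

    def test_merge_gap_bridges_nearby_peaks(self):
        v = np.zeros(10_000)
        v[1000:1200] = 5.0
        v[4000:4200] = 5.0
        c = np.zeros(10_000)
        c[8000:8010] = 0.5
        merged = call_peaks(track(v), track(c), merge_gap=5000,
                            min_separation=0.0)
        apart = call_peaks(track(v), track(c), merge_gap=1000,
                           min_separation=0.0)
        assert len(merged) == 1 and len(apart) == 2
        assert merged.peaks[0].total_signal == pytest.approx(2 * 200 * 5.0)

    def test_peaks_respect_reported_threshold(self):
        rng = np.random.default_rng(8)
        t = rng.poisson(0.8, size=2000).astype(float)
        t[500:540] += 12
        c = rng.poisson(0.8, size=2000).astype(float)
        ps = call_peaks(track(t), track(c))
        for p in ps.peaks:
            assert p.total_signal >= ps.threshold


class TestOracleEquivalence:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_small_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 1000))
        t = rng.poisson(0.6, size=n).astype(float)
        c = rng.poisson(0.6, size=n).astype(float)
        spikes = rng.integers(0, max(1, n - 10), size=3)
        for s in spikes:
            t[s:s + 8] += rng.integers(5, 20)
        got = call_peaks(track(t), track(c))
        want = oracle_call(t, c, "stringent")
        assert [(b.start, b.end) for b in got.peaks] == \
            [(b.start, b.end) for b in want]
        np.testing.assert_allclose([b.total_signal for b in got.peaks],
                                   [b.total_signal for b in want])

    def test_scaling_does_not_change_block_geometry(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(0.5, size=500).astype(float)
        b1 = signal_blocks(track(v))
        b2 = signal_blocks(track(3.0 * v))
        assert [(b.start, b.end) for b in b1] == [(b.start, b.end) for b in b2]


class TestOverlap:
    def make_peakset(self, ivs):
        return PeakSet([SignalBlock("chr1", s, e, 1.0, 1.0)
                        for s, e in ivs], threshold=0.0, mode="stringent")

    def test_partial_overlap_counts(self):
        ps = self.make_peakset([(100, 200)])
        iv = pd.DataFrame([("chr1", 150, 160, "a")],
                          columns=["chrom", "start", "end", "id"])
        out = overlap_with_intervals([ps], iv)
        assert bool(out["set1"][0]) is True

    def test_adjacent_half_open_do_not_overlap(self):
        ps = self.make_peakset([(100, 200)])
        iv = pd.DataFrame([("chr1", 200, 210, "a")],
                          columns=["chrom", "start", "end", "id"])
        out = overlap_with_intervals([ps], iv)
        assert bool(out["set1"][0]) is False

    def test_multiplicity_counts_peaksets(self):
        sets = [self.make_peakset([(100, 200)]) for _ in range(4)]
        sets += [self.make_peakset([(900, 950)]) for _ in range(3)]
        iv = pd.DataFrame([("chr1", 150, 160, "a")],
                          columns=["chrom", "start", "end", "id"])
        out = overlap_with_intervals(sets, iv)
        assert int(out["n_peaksets"][0]) == 4
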