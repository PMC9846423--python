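"""Trimming: Mott quality windows, mixed-peak windows, final intersection.

Both window searches are checked against exhaustive brute-force oracles
that enumerate every candidate window under the stated rules.
"""

import numpy as np
import pytest

from bsptrace.trace_io import ChromatogramTrace
from bsptrace.trimming import (TrimParams, final_trim, mixed_peak_trim,
                               mott_trim, non_mixed_mask, primary_peak_ratio)

from conftest import clean_trace, random_trace


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------

def mott_oracle(phred, cutoff):
    """All maximum-sum windows of (cutoff - p) scores, by O(L^2) enumeration."""
    c = cutoff - np.power(10.0, -np.asarray(phred, dtype=float) / 10.0)
    prefix = np.concatenate([[0.0], np.cumsum(c)])
    best = 0.0
    argmax = []
    L = len(c)
    for s in range(1, L + 1):
        for e in range(s, L + 1):
            total = prefix[e] - prefix[s - 1]
            if total > best + 1e-12:
                best = total
                argmax = [(s, e)]
            elif abs(total - best) <= 1e-12 and best > 0:
                argmax.append((s, e))
    return best, argmax


def mixed_oracle(mask, params):
    """Exhaustive search over all (start, end, n) triples."""
    L = len(mask)
    pref = np.concatenate([[0], np.cumsum(mask)])

    def all_non_mixed(a, b):  # 1-based inclusive
        return pref[b] - pref[a - 1] == b - a + 1

    for n in range(params.boundary_run_min, params.boundary_run_max + 1):
        best = None  # (length, -start, (s, e))
        for s in range(1, L + 1):
            for e in range(s + n - 1, L + 1):
                if all_non_mixed(s, s + n - 1) and all_non_mixed(e - n + 1, e):
                    cand = (e - s + 1, -s, (s, e))
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            s, e = best[2]
            frac = (pref[e] - pref[s - 1]) / (e - s + 1)
            if frac >= params.non_mixed_fraction_threshold:
                return (s, e)
    return None


def window_sum(phred, cutoff, window):
    p = np.power(10.0, -np.asarray(phred, dtype=float) / 10.0)
    s, e = window
    return float(np.sum(cutoff - p[s - 1:e]))


# ----------------------------------------------------------------------
# mott_trim
# ----------------------------------------------------------------------

class TestMottTrim:
    def test_uniformly_good_read_kept_whole(self):
        assert mott_trim([60] * 100, 0.001) == (1, 100)

    def test_uniformly_bad_read_rejected(self):
        assert mott_trim([10] * 100, 0.001) is None

    def test_interior_window(self):
        assert mott_trim([10, 10, 40, 40, 40, 10, 10], 0.001) == (3, 5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            L = int(rng.integers(1, 201))
            phred = rng.integers(0, 61, L)
            cutoff = 0.001
            got = mott_trim(phred, cutoff)
            best, argmax = mott_oracle(phred, cutoff)
            if best <= 0:
                assert got is None
            else:
                assert got is not None
                assert abs(window_sum(phred, cutoff, got) - best) < 1e-9


# ----------------------------------------------------------------------
# primary peak ratio / mixed-peak trimming
# ----------------------------------------------------------------------

class TestPrimaryPeakRatio:
    @pytest.mark.parametrize("heights,expected", [
        ((0, 100, 0, 0), 1.0),
        ((25, 25, 25, 25), 0.25),
        ((10, 75, 10, 5), 0.75),
    ])
    def test_examples(self, heights, expected):
        assert primary_peak_ratio(heights) == pytest.approx(expected)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError):
            primary_peak_ratio((0, 0, 0, 0))


def trace_from_mask(mask, phred=60):
    """Trace whose non-mixed pattern equals *mask* (pure vs flat peaks)."""
    L = len(mask)
    heights = np.full((L, 4), 25)
    heights[np.asarray(mask, dtype=bool), 0] = 1000
    return ChromatogramTrace("m", "A" * L, np.full(L, phred), heights)


class TestMixedPeakTrim:
    def test_all_non_mixed(self):
        win = mixed_peak_trim(trace_from_mask([True] * 50))
        assert win == (1, 50)

    def test_all_mixed(self):
        assert mixed_peak_trim(trace_from_mask([False] * 50)) is None

    def test_spec_pattern_against_oracle(self):
        mask = [True] * 5 + [False] * 20 + [True] * 10
        params = TrimParams()
        got = mixed_peak_trim(trace_from_mask(mask), params)
        assert got == mixed_oracle(np.asarray(mask), params)

    def test_ratio_tie_is_mixed(self):
        """A primary peak ratio of exactly the threshold counts as mixed."""
        heights = np.array([[10, 75, 10, 5]] * 10)  # ratio exactly 0.75
        t = ChromatogramTrace("t", "C" * 10, np.full(10, 60), heights)
        assert not non_mixed_mask(t, 0.75).any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = TrimParams()
        for _ in range(12):
            L = int(rng.integers(3, 81))
            mask = rng.random(L) < rng.uniform(0.3, 0.95)
            got = mixed_peak_trim(trace_from_mask(mask), params)
            assert got == mixed_oracle(mask, params)

    def test_monotonicity_in_ratio_threshold(self, rng):
        """Raising the primary-ratio threshold never lengthens the window.

        Holds for the geometric window search itself (checked here with the
        non-mixed-fraction filter disabled); the fraction filter can switch
        the selected boundary width and break global monotonicity.
        """
        for _ in range(10):
            t = random_trace(rng, 120)
            prev = None
            for thr in (0.5, 0.65, 0.8, 0.95):
                mask_len = int(non_mixed_mask(t, thr).sum())
                win = mixed_peak_trim(t, TrimParams(
                    primary_ratio_threshold=thr,
                    non_mixed_fraction_threshold=1e-9))
                length = 0 if win is None else win[1] - win[0] + 1
                if prev is not None:
                    assert length <= prev[0]
                    assert mask_len <= prev[1]
                prev = (length, mask_len)


# ----------------------------------------------------------------------
# final_trim
# ----------------------------------------------------------------------

class TestFinalTrim:
    def test_clean_read_fully_kept(self):
        read = final_trim(clean_trace(200))
        assert read.valid
        assert (read.start, read.end) == (1, 200)
        assert read.mean_phred == 60
        assert read.frac_non_mixed == 1.0

    def test_window_intersection(self):
        # quality good only in 10..150; peaks clean only in 50..200
        L = 200
        phred = np.full(L, 5)
        phred[9:150] = 60
        heights = np.full((L, 4), 25)
        heights[49:200, 0] = 1000
        t = ChromatogramTrace("t", "A" * L, phred, heights)
        read = final_trim(t)
        assert read.quality_window == (10, 150)
        assert read.mixed_window == (50, 200)
        assert (read.start, read.end) == (50, 150)
        assert read.valid

    def test_short_read_fails_min_length(self):
        read = final_trim(clean_trace(20))
        assert not read.valid
        assert "30" in read.failure_reason

    def test_low_mean_phred_fails(self):
        # At the default cutoff, Mott trimming already removes sub-Q30
        # windows, so exercise the gate with a raised threshold.
        read = final_trim(clean_trace(100, phred=45),
                          TrimParams(min_mean_phred=50))
        assert not read.valid
        assert "Phred" in read.failure_reason

    def test_final_window_subset_of_inputs(self, rng):
        for _ in range(20):
            t = random_trace(rng)
            read = final_trim(t)
            if not read.valid:
                continue
            (qs, qe), (ms, me) = read.quality_window, read.mixed_window
            assert qs <= read.start <= read.end <= qe
            assert ms <= read.start <= read.end <= me

    def test_idempotent(self, rng):
        """Trimming an already-trimmed read keeps the full window."""
        for _ in range(20):
            t = random_trace(rng)
            read = final_trim(t)
            if not read.valid:
                continue
            sub = ChromatogramTrace(
                "sub", t.called_bases[read.start - 1:read.end],
                t.phred[read.start - 1:read.end],
                t.peak_heights[read.start - 1:read.end])
            again = final_trim(sub)
            assert again.valid
            assert (again.start, again.end) == (1, len(sub))

    def test_failures_are_data_not_exceptions(self):
        t = ChromatogramTrace("t", "ACGT", [5, 5, 5, 5], np.full((4, 4), 25))
        read = final_trim(t)
        assert not read.valid
        assert read.failure_reason
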