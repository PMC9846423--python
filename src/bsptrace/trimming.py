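"""Read-extremity trimming by quality score and by mixed-peak signal.

Sanger read extremities carry off-scale signal and base-calling errors, so
a read is trimmed by two independent criteria before alignment:

1. **Mott quality trimming** — each base's Phred quality ``q`` is turned
   into an error probability ``p = 10**(-q/10)`` and scored
   ``cutoff - p``; the kept window is the maximum-sum contiguous segment of
   these scores (computed with the reset-to-zero running-sum variant).  The
   default cutoff of 0.001 corresponds to Phred 30.

2. **Mixed-peak trimming** — each base is labelled *non-mixed* when its
   primary peak ratio (tallest channel over the sum of the four channels)
   exceeds a threshold (default 0.75).  For each boundary width ``n`` from
   3 to 15, the longest window opening and closing with ``n`` consecutive
   non-mixed bases is a candidate; among candidates whose overall non-mixed
   fraction reaches the threshold (default 0.75) the one with the smallest
   ``n`` is kept.

The final trimmed read is the intersection of the two windows, re-checked
against minimum length, minimum mean Phred and the non-mixed fraction.  A
read failing any step is returned as an invalid :class:`TrimmedRead` (a
data outcome, not an exception): it will contribute no methylation values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import ChromatogramTrace

Window = tuple[int, int]  # 1-based inclusive (start, end)


@dataclass
class TrimParams:
    """Trimming thresholds; defaults follow the published workflow."""

    error_prob_cutoff: float = 0.001      # Mott cutoff, == Phred 30
    primary_ratio_threshold: float = 0.75
    non_mixed_fraction_threshold: float = 0.75
    boundary_run_min: int = 3
    boundary_run_max: int = 15
    min_length: int = 30
    min_mean_phred: float = 30.0

    def __post_init__(self):
        if not (0 < self.error_prob_cutoff < 1):
            raise ValueError("error_prob_cutoff must be in (0, 1)")
        for name in ("primary_ratio_threshold", "non_mixed_fraction_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.boundary_run_min > self.boundary_run_max:
            raise ValueError("boundary_run_min must be <= boundary_run_max")


@dataclass
class TrimmedRead:
    """A validated sub-interval of a chromatogram trace."""

    trace: ChromatogramTrace
    start: int = 0
    end: int = -1
    mean_phred: float = float("nan")
    frac_non_mixed: float = float("nan")
    quality_window: Window | None = None
    mixed_window: Window | None = None
    valid: bool = False
    failure_reason: str = ""

    @property
    def sequence(self) -> str:
        """Called bases of the kept window."""
        return self.trace.called_bases[self.start - 1:self.end]

    def __len__(self) -> int:
        return self.end - self.start + 1 if self.valid else 0

    def to_trace_position(self, p: int) -> int:
        """Map a 1-based trimmed-read position to the full-trace position."""
        return self.start + p - 1


def mott_trim(phred, error_prob_cutoff: float = 0.001) -> Window | None:
    """Maximum-scoring quality window (modified Mott algorithm, M1).

    Scores are ``cutoff - p`` per base.  The running sum is clipped below at
    zero; the returned window ends at the (first) argmax of the running sum
    and starts just after the last reset before it — the maximum-sum
    contiguous segment.  Returns ``None`` when no base scores positive.
    """
    phred = np.asarray(phred, dtype=float)
    scores = error_prob_cutoff - np.power(10.0, -phred / 10.0)
    best = 0.0
    best_end = None
    running = 0.0
    seg_start = 1
    win_start = 1
    for i, s in enumerate(scores, start=1):
        running += s
        if running <= 0:
            running = 0.0
            seg_start = i + 1
            continue
        if running > best:
            best = running
            best_end = i
            win_start = seg_start
    if best_end is None:
        return None
    return (win_start, best_end)


def primary_peak_ratio(heights) -> float:
    """Tallest of the four channel heights over their sum.

    Raises ``ValueError`` on all-zero heights (the caller treats such a
    base as mixed).
    """
    h = np.asarray(heights, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("primary peak ratio undefined for all-zero heights")
    return float(h.max() / total)


def non_mixed_mask(trace: ChromatogramTrace, threshold: float) -> np.ndarray:
    """Boolean per-base mask: primary peak ratio strictly above *threshold*.

    All-zero bases are mixed by definition.
    """
    h = trace.peak_heights.astype(float)
    total = h.sum(axis=1)
    ratio = np.divide(h.max(axis=1), total, out=np.zeros(len(h)), where=total > 0)
    return (ratio > threshold) & (total > 0)


def mixed_peak_trim(trace: ChromatogramTrace, params: TrimParams | None = None
                    ) -> Window | None:
    """Longest window bounded by clean (non-mixed) runs.

    For each boundary width ``n`` in ``boundary_run_min..boundary_run_max``
    the candidate is the longest window whose first *n* and last *n* bases
    are all non-mixed (leftmost on length ties).  Among candidates whose
    non-mixed fraction is >= ``non_mixed_fraction_threshold`` the one with
    the smallest *n* is returned; ``None`` when no candidate qualifies.
    """
    params = params or TrimParams()
    mask = non_mixed_mask(trace, params.primary_ratio_threshold)
    L = len(mask)
    if L == 0 or not mask.any():
        return None
    # run[i] = length of the non-mixed run starting at i (0-based)
    run = np.zeros(L, dtype=int)
    run[L - 1] = 1 if mask[L - 1] else 0
    for i in range(L - 2, -1, -1):
        run[i] = run[i + 1] + 1 if mask[i] else 0
    # rrun[i] = length of the non-mixed run ending at i
    rrun = np.zeros(L, dtype=int)
    rrun[0] = 1 if mask[0] else 0
    for i in range(1, L):
        rrun[i] = rrun[i - 1] + 1 if mask[i] else 0
    csum = np.concatenate([[0], np.cumsum(mask)])

    for n in range(params.boundary_run_min, params.boundary_run_max + 1):
        starts = np.flatnonzero(run >= n)       # window may start here
        ends = np.flatnonzero(rrun >= n)        # window may end here
        if len(starts) == 0 or len(ends) == 0:
            continue
        s = starts[0]
        # longest window: earliest valid start with the latest valid end
        valid_ends = ends[ends >= s + n - 1]
        if len(valid_ends) == 0:
            continue
        e = valid_ends[-1]
        frac = (csum[e + 1] - csum[s]) / (e - s + 1)
        if frac >= params.non_mixed_fraction_threshold:
            return (int(s) + 1, int(e) + 1)
    return None


def final_trim(trace: ChromatogramTrace, params: TrimParams | None = None
               ) -> TrimmedRead:
    """Intersect the quality and mixed-peak windows and validate the result.

    Failure (either criterion finds no window, empty intersection, or the
    final window misses the length / mean-Phred / non-mixed-fraction gates)
    yields an invalid :class:`TrimmedRead` carrying the reason.
    """
    params = params or TrimParams()
    qwin = mott_trim(trace.phred, params.error_prob_cutoff)
    mwin = mixed_peak_trim(trace, params)
    read = TrimmedRead(trace=trace, quality_window=qwin, mixed_window=mwin)
    if qwin is None:
        read.failure_reason = "quality trimming found no usable window"
        return read
    if mwin is None:
        read.failure_reason = "mixed-peak trimming found no usable window"
        return read
    start = max(qwin[0], mwin[0])
    end = min(qwin[1], mwin[1])
    if start > end:
        read.failure_reason = "quality and mixed-peak windows do not overlap"
        return read
    read.start, read.end = start, end
    window_phred = trace.phred[start - 1:end]
    read.mean_phred = float(np.mean(window_phred))
    mask = non_mixed_mask(trace, params.primary_ratio_threshold)[start - 1:end]
    read.frac_non_mixed = float(np.mean(mask))
    failures = []
    if end - start + 1 < params.min_length:
        failures.append(
            f"trimmed length {end - start + 1} < min length {params.min_length}")
    if read.mean_phred < params.min_mean_phred:
        failures.append(
            f"mean Phred {read.mean_phred:.1f} < {params.min_mean_phred}")
    if read.frac_non_mixed < params.non_mixed_fraction_threshold:
        failures.append(
            f"non-mixed fraction {read.frac_non_mixed:.2f} < "
            f"{params.non_mixed_fraction_threshold}")
    if failures:
        read.failure_reason = "; ".join(failures)
        return read
    read.valid = True
    return read
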