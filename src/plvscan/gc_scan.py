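"""Windowed GC tracks, GC-deviant segment calling, and element-vs-host GC deltas.

Endogenous polinton-like viruses typically differ from their host genome in
base composition by 10-30 percentage points over their whole 5-80 kb span, so
a coarse windowed GC track is a cheap, annotation-free triage signal for
candidate insertions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .seq_io import Contig, Interval, gc_fraction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCWindow:
    """One tiling window; gc is nan when every base in the window is N."""

    interval: Interval
    gc: float
    n_count: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.gc)


@dataclass(frozen=True)
class GCSegment:
    """A run of windows deviating from the host baseline in one direction."""

    interval: Interval
    mean_gc: float
    host_baseline_gc: float

    @property
    def delta_points(self) -> float:
        return 100.0 * (self.mean_gc - self.host_baseline_gc)


def windowed_gc(contig: Contig, window_bp: int = 500) -> list[GCWindow]:
    """Tile a contig with non-overlapping windows and compute per-window GC.

    The last window of a contig may be shorter than ``window_bp``. GC is
    computed over non-N bases only: (G+C)/(A+C+G+T).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    n = contig.length
    if n == 0:
        return []
    arr = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    # cumulative counts allow O(1) per-window sums
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    windows: list[GCWindow] = []
    for start in range(0, n, window_bp):
        end = min(start + window_bp, n)
        gc_count = int(cum_gc[end] - cum_gc[start])
        n_count = int(cum_n[end] - cum_n[start])
        denom = (end - start) - n_count
        gc = gc_count / denom if denom > 0 else float("nan")
        windows.append(
            GCWindow(Interval(contig.id, start, end), gc, n_count)
        )
    return windows


def call_gc_segments(
    windows: list[GCWindow],
    host_baseline: float,
    min_delta_points: float = 10.0,
    min_len_bp: int = 5000,
    max_len_bp: int = 80000,
) -> list[GCSegment]:
    """Call maximal runs of windows deviating from the host baseline.

    A run is a maximal stretch of windows whose |gc - baseline| exceeds the
    threshold with a consistent sign. One intervening non-deviant window is
    tolerated (nested host-like or GC-divergent insertions inside an element
    would otherwise split it); all-N windows neither break nor extend a run.
    Runs are reported when their genomic span is within [min_len, max_len].
    """
    if min_len_bp > max_len_bp:
        raise ValueError("min_len_bp must be <= max_len_bp")
    if not 0.0 <= host_baseline <= 1.0:
        raise ValueError("host_baseline must be in [0, 1]")
    thresh = min_delta_points / 100.0

    def sign_of(w: GCWindow) -> int:
        if not w.defined:
            return 0
        d = w.gc - host_baseline
        if d >= thresh:
            return 1
        if d <= -thresh:
            return -1
        return 0

    segments: list[GCSegment] = []
    run: list[int] = []  # indices of deviant windows in current run
    run_sign = 0
    pending_break = False

    def close_run() -> None:
        nonlocal run, run_sign, pending_break
        if run:
            first, last = windows[run[0]], windows[run[-1]]
            span = Interval(
                first.interval.contig_id, first.interval.start, last.interval.end
            )
            if min_len_bp <= span.length <= max_len_bp:
                covered = [
                    w
                    for w in windows[run[0] : run[-1] + 1]
                    if w.defined
                ]
                total = sum(w.interval.length - w.n_count for w in covered)
                mean_gc = (
                    sum(w.gc * (w.interval.length - w.n_count) for w in covered) / total
                )
                segments.append(GCSegment(span, mean_gc, host_baseline))
        run = []
        run_sign = 0
        pending_break = False

    for i, w in enumerate(windows):
        if not w.defined:
            continue  # N-only windows never break or extend a run
        s = sign_of(w)
        if s == 0:
            if run:
                if pending_break:
                    close_run()
                else:
                    pending_break = True
            continue
        if run and s != run_sign:
            close_run()
        if not run:
            run_sign = s
        run.append(i)
        pending_break = False
    close_run()
    return segments


def element_gc_delta(
    element: Interval,
    contig: Contig,
    flank_bp: int = 10000,
    neighbor_elements: list[Interval] | None = None,
    assembly_gc: float | None = None,
) -> float:
    """Signed GC difference, in percentage points, between an element and its flanks.

    Flanks of ``flank_bp`` on either side are truncated at contig ends and at
    adjacent annotated elements. If the element covers the whole contig the
    delta is computed against ``assembly_gc`` (warning logged).
    """
    if element.contig_id != contig.id or element.end > contig.length:
        raise ValueError("element does not lie inside contig")
    elem_gc = gc_fraction(contig.seq[element.start : element.end])

    left_lo, left_hi = max(0, element.start - flank_bp), element.start
    right_lo, right_hi = element.end, min(contig.length, element.end + flank_bp)
    for other in neighbor_elements or []:
        if other.contig_id != contig.id or other.overlaps(element):
            continue
        if other.end <= element.start:
            left_lo = max(left_lo, other.end)
        if other.start >= element.end:
            right_hi = min(right_hi, other.start)
    flank_seq = contig.seq[left_lo:left_hi] + contig.seq[right_lo:right_hi]
    if not flank_seq:
        baseline = assembly_gc if assembly_gc is not None else gc_fraction(contig.seq)
        logger.warning(
            "element %s:%d-%d has no host flank; using assembly-wide baseline",
            element.contig_id,
            element.start,
            element.end,
        )
        return 100.0 * (elem_gc - baseline)
    return 100.0 * (elem_gc - gc_fraction(flank_seq))


def write_gc_track(windows: list[GCWindow], path) -> None:
    """Export a GC track as bedGraph-style TSV (contig, start, end, gc)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\tgc\n")
        for w in windows:
            gc = "NA" if not w.defined else f"{w.gc:.4f}"
            fh.write(
                f"{w.interval.contig_id}\t{w.interval.start}\t{w.interval.end}\t{gc}\n"
            )
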