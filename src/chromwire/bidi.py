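"""Bidirectional-transcription (eRNA) detection from stranded coverage.

Active enhancers produce short divergent transcripts: plus-strand reads
downstream and minus-strand reads upstream of a nucleosome-depleted center.
A sliding window passes when both strands are transcribed (the minor strand
carries at least 20% of the major strand's reads), the geometry is divergent
(minus-strand centroid 5' of the plus-strand centroid, each strand
concentrated on its own half of the window), and the window does not look
like ordinary gene transcription (no TSS overlap, not exonic on both
strands).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, IntervalSet, SignalTrack

__all__ = ["BidiLocus", "detect_bidirectional"]


@dataclasses.dataclass(frozen=True)
class BidiLocus:
    interval: GenomicInterval
    plus_reads: float
    minus_reads: float

    @property
    def minor_ratio(self) -> float:
        hi = max(self.plus_reads, self.minus_reads)
        lo = min(self.plus_reads, self.minus_reads)
        return lo / hi if hi > 0 else 0.0


def _window_passes(
    plus: SignalTrack,
    minus: SignalTrack,
    chrom: str,
    start: int,
    end: int,
    min_minor_ratio: float,
    min_major_reads: float,
    min_centroid_gap: float,
    min_half_concentration: float,
) -> bool:
    p = plus.sum_in(chrom, start, end)
    m = minus.sum_in(chrom, start, end)
    major, minor = max(p, m), min(p, m)
    if major < min_major_reads or major == 0:
        return False
    if minor / major < min_minor_ratio:
        return False
    # divergent geometry: minus mass 5' (left) of plus mass
    cp = plus.centroid_in(chrom, start, end)
    cm = minus.centroid_in(chrom, start, end)
    if not np.isfinite(cp) or not np.isfinite(cm):
        return False
    if cp - cm < min_centroid_gap:
        return False
    mid = (start + end) / 2.0
    plus_right = plus.sum_in(chrom, int(mid), end)
    minus_left = minus.sum_in(chrom, start, int(mid))
    if p > 0 and plus_right / p < min_half_concentration:
        return False
    if m > 0 and minus_left / m < min_half_concentration:
        return False
    return True


def detect_bidirectional(
    plus: SignalTrack,
    minus: SignalTrack,
    window: int = 1000,
    step: int = 100,
    min_minor_ratio: float = 0.2,
    min_major_reads: float = 10.0,
    tss: IntervalSet | None = None,
    exons_plus: IntervalSet | None = None,
    exons_minus: IntervalSet | None = None,
    min_centroid_gap: float = 100.0,
    min_half_concentration: float = 0.6,
) -> list[BidiLocus]:
    """Scan stranded coverage for divergently transcribed loci.

    Windows of ``window`` bp slide every ``step`` bp over the covered extent
    of each chromosome. A window passes iff (i) the major strand carries at
    least ``min_major_reads``, (ii) the minor/major read ratio is at least
    ``min_minor_ratio``, (iii) the geometry is divergent: the minus-strand
    centroid lies at least ``min_centroid_gap`` bp 5' of the plus-strand
    centroid and each strand has at least ``min_half_concentration`` of its
    reads on its own half of the window, and (iv) the window overlaps no TSS
    and is not exonic on both strands. Overlapping passing windows are
    merged; merged loci report summed strand counts over the union,
    extended to whole overlapping coverage segments, and must themselves
    satisfy the minor-ratio rule.
    """
    chroms = sorted(set(plus.data) | set(minus.data))
    passing_rows = []
    for chrom in chroms:
        lo, hi = np.inf, -np.inf
        for track in (plus, minus):
            if chrom in track.data:
                s, e, _ = track.data[chrom]
                if s.size:
                    lo = min(lo, int(s[0]))
                    hi = max(hi, int(e[-1]))
        if not np.isfinite(lo):
            continue
        first = max(0, (int(lo) - window) // step * step)
        for start in range(first, int(hi) + step, step):
            end = start + window
            if plus.sum_in(chrom, start, end) == 0 and minus.sum_in(chrom, start, end) == 0:
                continue
            if not _window_passes(plus, minus, chrom, start, end, min_minor_ratio,
                                  min_major_reads, min_centroid_gap, min_half_concentration):
                continue
            passing_rows.append((chrom, start, end))
    if not passing_rows:
        return []
    candidate = IntervalSet(pd.DataFrame(passing_rows, columns=["chrom", "start", "end"])).merge()
    # annotation exclusion on the merged loci (a window-level exclusion would
    # let a TSS-straddling locus survive via its flanking windows)
    if tss is not None and len(tss):
        candidate = candidate.filter_overlapping(tss, invert=True)
    if exons_plus is not None and exons_minus is not None and len(candidate):
        both = candidate.overlap_mask(exons_plus) & candidate.overlap_mask(exons_minus)
        candidate = IntervalSet(candidate.df[~both])
    out = []
    for row in candidate.df.itertuples(index=False):
        # expand to whole overlapping coverage segments before the final
        # ratio check: a window clipping the major-strand peak would
        # otherwise inflate the minor ratio at locus boundaries
        start, end = int(row.start), int(row.end)
        for track in (plus, minus):
            if row.chrom not in track.data:
                continue
            s, e, _ = track.data[row.chrom]
            lo = np.searchsorted(e, start, side="right")
            hi = np.searchsorted(s, end, side="left")
            if hi > lo:
                start = min(start, int(s[lo]))
                end = max(end, int(e[hi - 1]))
        p = plus.sum_in(row.chrom, start, end)
        m = minus.sum_in(row.chrom, start, end)
        locus = BidiLocus(GenomicInterval(row.chrom, int(row.start), int(row.end)),
                          plus_reads=p, minus_reads=m)
        if max(p, m) >= min_major_reads and locus.minor_ratio >= min_minor_ratio:
            out.append(locus)
    return out


def loci_to_intervalset(loci: Sequence[BidiLocus]) -> IntervalSet:
    rows = [(l.interval.chrom, l.interval.start, l.interval.end, "bidi", l.minor_ratio, ".")
            for l in loci]
    if not rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]))
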