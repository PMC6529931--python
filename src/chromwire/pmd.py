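"""Partially methylated domain (PMD) calling and consensus.

PMDs are megabase-scale regions of intermediate, disordered DNA methylation
associated with heterochromatin and late replication. They are called per
sample by scanning the methylome with a sliding window and keeping merged
stretches of hypomethylated windows; a cross-sample consensus keeps the
bases supported by at least a fraction of the cohort.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    IntervalSet,
    MethylomeTrack,
    SignalTrack,
    aggregate_around_anchors,
    coverage_consensus,
    merge_intervals,
)

__all__ = [
    "PMDParams",
    "call_pmds",
    "consensus_pmds",
    "pmd_boundary_profiles",
    "feature_in_pmd_fraction",
]


@dataclasses.dataclass
class PMDParams:
    """Window-scan parameters for PMD calling.

    A window qualifies iff it contains at least one CpG and its mean beta is
    strictly below ``max_mean_beta``; qualifying windows are merged and
    merged regions over ``min_length`` bp long are reported. Regions
    overlapping ``gap_regions`` (assembly gaps: centromeres, telomeres) by
    one or more bases are discarded.
    """

    window: int = 10_000
    step: int = 1_000
    max_mean_beta: float = 0.65
    min_length: int = 100_000
    gap_regions: IntervalSet | None = None

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not 0.0 < self.max_mean_beta < 1.0:
            raise ValueError("max_mean_beta must be in (0, 1)")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")


def _qualifying_windows(pos: np.ndarray, beta: np.ndarray, p: PMDParams) -> tuple[np.ndarray, np.ndarray]:
    """Starts/ends of sliding windows whose CpG mean beta < max_mean_beta.

    Windows are placed at every multiple of ``step`` from 0 through the last
    placement covering the final CpG. Windows with zero CpGs never qualify:
    absence of data is not evidence of hypomethylation.
    """
    last_start = (int(pos[-1]) // p.step) * p.step
    starts = np.arange(0, last_start + p.step, p.step, dtype=np.int64)
    ends = starts + p.window
    csum = np.concatenate([[0.0], np.cumsum(beta)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.inf)
    ok = (n > 0) & (means < p.max_mean_beta)
    return starts[ok], ends[ok]


def call_pmds(m: MethylomeTrack, p: PMDParams | None = None) -> IntervalSet:
    """Call PMDs from one sample's methylome.

    Scans each chromosome with windows of ``p.window`` bp placed every
    ``p.step`` bp; windows with CpG mean beta < ``p.max_mean_beta`` are
    merged (overlapping or touching) and merged regions over
    ``p.min_length`` bp long are returned with their region mean beta in
    the score column. Regions overlapping gap annotation are discarded.
    """
    p = p or PMDParams()
    if len(m) == 0:
        raise ValueError("empty methylome track")
    rows = []
    for chrom in m.chroms:
        pos = m.positions(chrom)
        beta = m.betas(chrom)
        if pos.size == 0:
            warnings.warn(f"chromosome {chrom} has no CpGs; skipped")
            continue
        ws, we = _qualifying_windows(pos, beta, p)
        if ws.size == 0:
            continue
        merged = merge_intervals(IntervalSet(pd.DataFrame({"chrom": chrom, "start": ws, "end": we})))
        for _, row in merged.df.iterrows():
            if row["end"] - row["start"] > p.min_length:
                lo = np.searchsorted(pos, row["start"], side="left")
                hi = np.searchsorted(pos, row["end"], side="left")
                mean_beta = float(beta[lo:hi].mean()) if hi > lo else math.nan
                rows.append((chrom, int(row["start"]), int(row["end"]), mean_beta))
    if not rows:
        return IntervalSet.empty()
    out = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))
    if p.gap_regions is not None and len(p.gap_regions):
        out = out.filter_overlapping(p.gap_regions, invert=True)
    return out


def consensus_pmds(pmd_sets: Sequence[IntervalSet], min_fraction: float = 0.5) -> IntervalSet:
    """Consensus PMDs: bases covered by PMDs in at least ceil(min_fraction * n)
    of the samples, merged. With 11 samples at min_fraction 0.5 the threshold
    is 6 samples.
    """
    if not pmd_sets:
        raise ValueError("need at least one PMD set")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    min_count = math.ceil(min_fraction * len(pmd_sets))
    return coverage_consensus(list(pmd_sets), min_count=max(min_count, 1))


def pmd_boundaries_as_anchors(pmds: IntervalSet) -> list[tuple[str, int, str]]:
    """Two oriented anchors per PMD: the left boundary (interior rightward,
    orientation '+') and the right boundary (interior leftward, '-')."""
    anchors = []
    for row in pmds.df.itertuples(index=False):
        anchors.append((row.chrom, int(row.start), "+"))
        anchors.append((row.chrom, int(row.end), "-"))
    return anchors


def pmd_boundary_profiles(
    tracks: Mapping[str, SignalTrack],
    pmds: IntervalSet,
    flank: int = 50_000,
    bin_size: int = 5_000,
) -> dict[str, np.ndarray]:
    """Flank-normalized aggregate signal profiles around PMD boundaries.

    For each named track, averages the signal in ``bin_size`` windows over
    +/- ``flank`` around every PMD boundary, orienting both boundaries so the
    domain interior falls on the same side, then divides by the mean over the
    outside-flank bins. Defaults give a 20-bin profile (100 kb / 5 kb).
    """
    anchors = pmd_boundaries_as_anchors(pmds)
    return {
        name: aggregate_around_anchors(track, anchors, flank=flank, bin_size=bin_size,
                                       normalize="flank_outside")
        for name, track in tracks.items()
    }


def feature_in_pmd_fraction(
    points: Sequence[tuple[str, int]],
    pmds: IntervalSet,
    genome_length: int,
) -> tuple[float, float]:
    """Observed fraction of point features (e.g. somatic mutations) inside
    PMDs versus the fraction expected from PMD genomic extent alone."""
    total_pmd = pmds.total_length()
    if genome_length < total_pmd:
        raise ValueError("genome_length smaller than total PMD length")
    expected = total_pmd / genome_length
    if not points:
        warnings.warn("empty point list; observed fraction undefined")
        return math.nan, expected
    chroms = [c for c, _ in points]
    pos = [p for _, p in points]
    inside = pmds.contains_points(chroms, pos)
    return float(inside.mean()), expected
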