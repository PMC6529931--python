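"""Active-enhancer annotation from ATAC/eRNA evidence and chromatin states.

Candidate loci (ATAC peaks or bidirectional-transcription loci) become
active enhancers when the +/- 1 kb region around their signal center falls
in a predicted active-enhancer chromatin state (states 1 and 9 of a 12-state
segmentation, both carrying H3K4me1 with strong H3K27ac) and does not sit on
a promoter. Per-sample lists built from replicate-consistent loci are then
combined into disease and control consensus sets by base-level occupancy.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence, Set

import pandas as pd

from .genomic_io import IntervalSet, coverage_consensus, merge_intervals

__all__ = [
    "ChromatinStateTrack",
    "EnhancerList",
    "replicate_consistent_loci",
    "active_enhancers",
    "consensus_enhancers",
]

VALID_STATES = set(range(1, 13))


class ChromatinStateTrack:
    """A chromatin-state segmentation: non-overlapping intervals labelled
    with a state in 1..12. The ``name`` column of the BED carries the label.
    """

    def __init__(self, intervals: IntervalSet):
        if "name" not in intervals.df.columns:
            raise ValueError("state track needs a label (name) column")
        labels = intervals.df["name"].astype(int)
        if not set(labels).issubset(VALID_STATES):
            raise ValueError("state labels must be in 1..12")
        df = intervals.df.copy()
        df["state"] = labels
        self.intervals = IntervalSet(df)

    @classmethod
    def read_bed(cls, path) -> "ChromatinStateTrack":
        return cls(IntervalSet.read_bed(path))

    def subset(self, states: Set[int]) -> IntervalSet:
        df = self.intervals.df
        return IntervalSet(df[df["state"].isin(states)])


@dataclasses.dataclass
class EnhancerList:
    sample: str
    evidence: str  # 'ATAC' or 'Bidi'
    loci: IntervalSet

    def __post_init__(self) -> None:
        if self.evidence not in {"ATAC", "Bidi"}:
            raise ValueError("evidence must be 'ATAC' or 'Bidi'")


def replicate_consistent_loci(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Loci of rep1 that overlap (>= 1 bp) a rep2 locus; reported with the
    rep1 coordinates."""
    return rep1.filter_overlapping(rep2)


def active_enhancers(
    loci: IntervalSet,
    states: ChromatinStateTrack,
    active_states: Set[int] = frozenset({1, 9}),
    flank: int = 1000,
    tss: IntervalSet | None = None,
    promoter_exclusion: int = 1000,
    sample: str = "",
    evidence: str = "ATAC",
) -> EnhancerList:
    """One sample's active enhancers.

    The +/- ``flank`` region around each locus center (interval midpoint) is
    kept iff it overlaps an active-state segment; regions overlapping a TSS
    +/- ``promoter_exclusion`` are dropped; surviving regions are merged.
    """
    if len(loci) == 0:
        return EnhancerList(sample=sample, evidence=evidence, loci=IntervalSet.empty())
    mid = (loci.df["start"] + loci.df["end"]) // 2
    regions = IntervalSet(pd.DataFrame({
        "chrom": loci.df["chrom"],
        "start": (mid - flank).clip(lower=0),
        "end": mid + flank,
    }))
    active = states.subset(active_states)
    regions = regions.filter_overlapping(active)
    if tss is not None and len(tss):
        excl = IntervalSet(pd.DataFrame({
            "chrom": tss.df["chrom"],
            "start": (tss.df["start"] - promoter_exclusion).clip(lower=0),
            "end": tss.df["end"] + promoter_exclusion,
        }))
        regions = regions.filter_overlapping(excl, invert=True)
    return EnhancerList(sample=sample, evidence=evidence, loci=merge_intervals(regions))


def consensus_enhancers(
    cll_lists: Sequence[EnhancerList],
    nbc_lists: Sequence[EnhancerList],
    min_cll: int = 3,
    min_nbc: int | None = None,
) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Consensus enhancer sets for the two conditions plus their overlap.

    ATAC- and eRNA-derived lists are never mixed in one consensus; the input
    lists must share one evidence kind. The control-side minimum defaults to
    1 list for ATAC evidence and 2 for Bidi (eRNA detection is the noisier
    assay). Consensus is base-level: bases covered by at least ``min_cll``
    disease lists (resp. ``min_nbc`` control lists), merged. The shared set
    is the merged intersection of the two consensus sets.
    """
    kinds = {l.evidence for l in list(cll_lists) + list(nbc_lists)}
    if len(kinds) > 1:
        raise ValueError(f"cannot mix evidence kinds in one consensus: {sorted(kinds)}")
    evidence = kinds.pop() if kinds else "ATAC"
    if min_nbc is None:
        min_nbc = 1 if evidence == "ATAC" else 2
    if len(cll_lists) < min_cll or len(nbc_lists) < min_nbc:
        warnings.warn("fewer lists than the consensus minimum; empty consensus")
    cll = coverage_consensus([l.loci for l in cll_lists], min_count=min_cll) \
        if len(cll_lists) >= min_cll else IntervalSet.empty()
    nbc = coverage_consensus([l.loci for l in nbc_lists], min_count=min_nbc) \
        if len(nbc_lists) >= min_nbc else IntervalSet.empty()
    shared = coverage_consensus([cll, nbc], min_count=2)
    return cll, nbc, shared
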