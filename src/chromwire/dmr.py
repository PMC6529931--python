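"""Differentially methylated region (DMR) calling and the B-cell-maturation filter.

A DMR is a run of consecutive CpGs that are individually significant and
shifted in the same direction, long enough (>= 200 bp) and strong enough
(|mean beta difference| >= 0.3). Because malignant B cells derive from
normal B cells at varying maturation stages, regions that shift similarly
during normal naive -> memory maturation are filtered out: only changes in
excess of the maturation programme are disease-specific.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, MethylomeTrack

__all__ = ["CpGStat", "DMR", "test_cpgs", "call_dmrs", "maturation_filter"]


@dataclasses.dataclass(frozen=True)
class CpGStat:
    """Per-CpG two-group comparison: delta = mean beta(group1) - mean beta(group2)."""

    chrom: str
    position: int
    delta: float
    pvalue: float

    def __post_init__(self) -> None:
        if abs(self.delta) > 1 + 1e-12:
            raise ValueError("|delta| cannot exceed 1 for beta values")


@dataclasses.dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    mean_delta: float
    n_cpgs: int
    direction: str  # 'hypo' (group1 lower) or 'hyper'

    def __post_init__(self) -> None:
        if self.direction not in {"hypo", "hyper"}:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")


def _beta_matrix(tracks: Sequence[MethylomeTrack]) -> pd.DataFrame:
    frames = []
    for i, t in enumerate(tracks):
        name = t.sample or f"s{i}"
        frames.append(t.df.set_index(["chrom", "pos"])["beta"].rename(name))
    return pd.concat(frames, axis=1)


def test_cpgs(
    group1: Sequence[MethylomeTrack],
    group2: Sequence[MethylomeTrack],
    min_samples: int = 2,
) -> list[CpGStat]:
    """Per-CpG two-sample location test on beta values across samples.

    CpGs are matched by (chrom, position); a site enters only if covered in
    at least ``min_samples`` samples of each group. The test is Welch's
    t-test on the per-sample betas; the effect is the difference of group
    means (group1 - group2). A site where both groups are constant and equal
    gets p = 1; constant-but-different sites get p = 0.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need >= 2 samples per group")
    b1 = _beta_matrix(group1)
    b2 = _beta_matrix(group2)
    common = b1.index.intersection(b2.index)
    b1 = b1.loc[common]
    b2 = b2.loc[common]
    n1 = b1.notna().sum(axis=1)
    n2 = b2.notna().sum(axis=1)
    keep = (n1 >= min_samples) & (n2 >= min_samples)
    b1, b2 = b1[keep], b2[keep]
    x1 = b1.to_numpy(dtype=float)
    x2 = b2.to_numpy(dtype=float)
    m1 = np.nanmean(x1, axis=1)
    m2 = np.nanmean(x2, axis=1)
    delta = m1 - m2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(x1, x2, axis=1, equal_var=False, nan_policy="omit")
    # degenerate zero-variance sites: equal means are null, unequal are certain
    pvals = np.where(np.isnan(pvals), np.where(np.abs(delta) > 0, 0.0, 1.0), pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out = [
        CpGStat(chrom=str(chrom), position=int(pos), delta=float(d), pvalue=float(p))
        for (chrom, pos), d, p in zip(b1.index, delta, pvals)
    ]
    out.sort(key=lambda s: (s.chrom, s.position))
    return out


def call_dmrs(
    stats_list: Sequence[CpGStat],
    alpha: float = 0.05,
    min_length: int = 200,
    min_delta: float = 0.3,
    max_cpg_gap: int = 500,
) -> list[DMR]:
    """Group significant CpGs into DMRs.

    Runs of consecutive CpGs with p < alpha and same-sign delta, with
    inter-CpG gaps <= max_cpg_gap bp, are merged into candidate regions. A
    region is reported iff its genomic span is >= min_length bp and the
    absolute mean delta over its CpGs is >= min_delta. Significance is
    strict (<); length and delta thresholds are inclusive (>=).
    """
    runs: list[list[CpGStat]] = []
    current: list[CpGStat] = []
    for s in sorted(stats_list, key=lambda x: (x.chrom, x.position)):
        significant = s.pvalue < alpha and s.delta != 0
        if not significant:
            if current:
                runs.append(current)
                current = []
            continue
        if current:
            prev = current[-1]
            same_chrom = s.chrom == prev.chrom
            close = same_chrom and (s.position - prev.position) <= max_cpg_gap
            same_sign = np.sign(s.delta) == np.sign(prev.delta)
            if not (close and same_sign):
                runs.append(current)
                current = []
        current.append(s)
    if current:
        runs.append(current)

    out: list[DMR] = []
    for run in runs:
        start = run[0].position
        end = run[-1].position + 1  # half-open, covers the last CpG base
        span = end - start
        mean_delta = float(np.mean([s.delta for s in run]))
        if span >= min_length and abs(mean_delta) >= min_delta:
            out.append(
                DMR(
                    interval=GenomicInterval(run[0].chrom, start, end),
                    mean_delta=mean_delta,
                    n_cpgs=len(run),
                    direction="hypo" if mean_delta < 0 else "hyper",
                )
            )
    return out


def maturation_filter(
    dmrs: Sequence[DMR],
    maturation_delta: Mapping[tuple[str, int, int], float],
    min_excess: float = 0.2,
) -> list[DMR]:
    """Remove DMRs explained by normal B-cell maturation.

    ``maturation_delta`` maps each DMR region (chrom, start, end) to the beta
    change observed between high-maturity memory and naive B cells. A DMR is
    kept iff its own mean delta differs from the maturation delta by at
    least ``min_excess``; similar changes (difference < 0.2 by default) are
    attributed to maturation, not disease. Missing maturation values are
    treated as 0 (region unchanged during maturation) with a warning.
    """
    kept = []
    for d in dmrs:
        key = (d.interval.chrom, d.interval.start, d.interval.end)
        if key in maturation_delta:
            mat = maturation_delta[key]
        else:
            warnings.warn(f"no maturation delta for {key}; assuming 0")
            mat = 0.0
        if abs(d.mean_delta - mat) >= min_excess:
            kept.append(d)
    return kept


def dmrs_to_dataframe(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """BED6-style table: name = direction, score = mean delta."""
    return pd.DataFrame(
        [
            (d.interval.chrom, d.interval.start, d.interval.end, d.direction,
             d.mean_delta, ".", d.n_cpgs)
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "name", "score", "strand", "n_cpgs"],
    )
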