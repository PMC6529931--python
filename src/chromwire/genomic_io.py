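"""Interval algebra, genomic track containers, and anchored signal aggregation.

All coordinates are 0-based half-open (BED convention). Readers that accept
1-based input convert on read. These containers and operations are shared by
every pipeline stage: methylome windowing, peak/state intersection, consensus
building, and boundary-profile aggregation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "MethylomeTrack",
    "ParseError",
    "read_methylome",
    "merge_intervals",
    "coverage_consensus",
    "aggregate_around_anchors",
    "nearest_distance_histogram",
]


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start < end required, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A collection of genomic intervals, stored sorted by (chrom, start).

    Backed by a pandas DataFrame with at least ``chrom``, ``start``, ``end``
    columns; extra columns (``name``, ``score``, ``strand``, state labels,
    roles, ...) ride along through sorting and serialization but not through
    merging, which returns bare coordinates.
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires column {col!r}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["start"] >= df["end"]).any():
                raise ValueError("empty or inverted interval (start >= end)")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [dataclasses.asdict(iv) for iv in intervals]
        if not rows:
            return cls.empty()
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        """Build from (chrom, start, end[, ...extra]) tuples."""
        rows = list(tuples)
        if not rows:
            return cls.empty()
        ncol = len(rows[0])
        cols = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
        return cls(pd.DataFrame(rows, columns=cols))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame({"chrom": pd.Series(dtype=str),
                                 "start": pd.Series(dtype=np.int64),
                                 "end": pd.Series(dtype=np.int64)}))

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        """Read BED3/BED6(+). Extra columns are kept under BED field names."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        names = ["chrom", "start", "end", "name", "score", "strand"]
        extra = [f"col{i}" for i in range(6, df.shape[1])]
        df.columns = (names + extra)[: df.shape[1]]
        return cls(df)

    def write_bed(self, path: str | Path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    # -- basic views -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        known = {f.name for f in dataclasses.fields(GenomicInterval)}
        for row in self.df.itertuples(index=False):
            d = {k: v for k, v in row._asdict().items() if k in known and pd.notna(v)}
            yield GenomicInterval(**d)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def total_length(self) -> int:
        """Total covered bases after merging overlaps."""
        m = self.merge()
        return int((m.df["end"] - m.df["start"]).sum())

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"] + self.df["end"]) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})

    # -- algebra -----------------------------------------------------------
    def merge(self, min_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, min_gap=min_gap)

    def overlap_mask(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: overlaps (>= 1 bp) any interval of other."""
        mask = np.zeros(len(self.df), dtype=bool)
        other_merged = other.merge()
        for chrom in self.chroms:
            idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
            if idx.size == 0:
                continue
            ostart, oend = other_merged.arrays(chrom)
            if ostart.size == 0:
                continue
            s = self.df["start"].to_numpy()[idx]
            e = self.df["end"].to_numpy()[idx]
            # candidate: last other-interval starting before e
            j = np.searchsorted(ostart, e, side="left") - 1
            valid = j >= 0
            hit = np.zeros_like(valid)
            hit[valid] = oend[j[valid]] > s[valid]
            mask[idx] = hit
        return mask

    def filter_overlapping(self, other: "IntervalSet", invert: bool = False) -> "IntervalSet":
        mask = self.overlap_mask(other)
        if invert:
            mask = ~mask
        return IntervalSet(self.df[mask])

    def contains_points(self, chrom: Sequence[str], pos: Sequence[int]) -> np.ndarray:
        """Boolean per point: inside any (merged) interval."""
        merged = self.merge()
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            s, e = merged.arrays(str(c))
            if s.size == 0:
                continue
            sel = chrom == c
            j = np.searchsorted(s, pos[sel], side="right") - 1
            ok = j >= 0
            inside = np.zeros(ok.shape, dtype=bool)
            inside[ok] = pos[sel][ok] < e[j[ok]]
            out[sel] = inside
        return out


def merge_intervals(s: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Merge overlapping intervals; two intervals merge iff the gap between
    them is <= min_gap. Touching half-open intervals merge at min_gap = 0.
    Idempotent. Returns bare (chrom, start, end) coordinates.
    """
    out_rows = []
    for chrom in s.chroms:
        start, end = s.arrays(chrom)
        if start.size == 0:
            continue
        cur_s, cur_e = start[0], end[0]
        for a, b in zip(start[1:], end[1:]):
            if a - cur_e <= min_gap:
                cur_e = max(cur_e, b)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = a, b
        out_rows.append((chrom, cur_s, cur_e))
    if not out_rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(out_rows, columns=["chrom", "start", "end"]))


def coverage_consensus(sets: Sequence[IntervalSet], min_count: int) -> IntervalSet:
    """Maximal regions where at least ``min_count`` of the input sets overlap.

    Occupancy is counted at base level: each input set contributes depth 1
    over its merged coverage, and the consensus is the merged set of bases
    with depth >= min_count. min_count greater than the number of sets yields
    an empty set.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if min_count > len(sets):
        return IntervalSet.empty()
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        merged = s.merge()
        for chrom in merged.chroms:
            start, end = merged.arrays(chrom)
            ev = events.setdefault(chrom, [])
            ev.extend((int(a), +1) for a in start)
            ev.extend((int(b), -1) for b in end)
    out_rows = []
    for chrom, ev in sorted(events.items()):
        ev.sort()
        depth = 0
        region_start = None
        for pos, delta in ev:
            new_depth = depth + delta
            if depth < min_count <= new_depth:
                region_start = pos
            elif new_depth < min_count <= depth:
                if pos > region_start:
                    out_rows.append((chrom, region_start, pos))
                region_start = None
            depth = new_depth
    if not out_rows:
        return IntervalSet.empty()
    return merge_intervals(IntervalSet(pd.DataFrame(out_rows, columns=["chrom", "start", "end"])))


class SignalTrack:
    """Piecewise-constant signal (bedGraph semantics): per chromosome, sorted
    non-overlapping [start, end) intervals with a real value. Bases not
    covered by any interval carry missing signal (not zero).
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        # chrom -> (starts, ends, values), starts strictly increasing
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (s, e, v) in data.items():
                self.add_chrom(chrom, s, e, v)

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=float)
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if s.size and (np.diff(s) <= 0).any():
            raise ValueError(f"{chrom}: interval starts must be strictly increasing")
        if s.size and (e[:-1] > s[1:]).any():
            raise ValueError(f"{chrom}: overlapping signal intervals")
        if not np.isfinite(v).all():
            raise ValueError(f"{chrom}: non-finite signal values")
        self.data[chrom] = (s, e, v)

    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"], dtype={"chrom": str})
        track = cls()
        for chrom, sub in df.groupby("chrom", sort=True):
            track.add_chrom(str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy(),
                            sub["value"].to_numpy())
        return track

    def write_bedgraph(self, path: str | Path) -> None:
        frames = []
        for chrom in sorted(self.data):
            s, e, v = self.data[chrom]
            frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)

    def total_signal(self) -> float:
        """Sum of value * length over all intervals (library size proxy)."""
        total = 0.0
        for s, e, v in self.data.values():
            total += float(np.sum((e - s) * v))
        return total

    def scale(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for chrom, (s, e, v) in self.data.items():
            out.add_chrom(chrom, s.copy(), e.copy(), v * factor)
        return out

    def _overlap_stats(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(weighted signal sum, covered bases) over [start, end)."""
        if chrom not in self.data or end <= start:
            return 0.0, 0
        s, e, v = self.data[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return 0.0, 0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.sum(ov * v[lo:hi])), int(np.sum(ov))

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Base-weighted mean signal over [start, end); NaN if no base covered."""
        wsum, nbases = self._overlap_stats(chrom, start, end)
        return wsum / nbases if nbases else float("nan")

    def sum_in(self, chrom: str, start: int, end: int) -> float:
        """Signal mass (value x covered bases) over [start, end)."""
        return self._overlap_stats(chrom, start, end)[0]

    def centroid_in(self, chrom: str, start: int, end: int) -> float:
        """Signal-weighted mean position over [start, end); NaN if massless."""
        if chrom not in self.data or end <= start:
            return float("nan")
        s, e, v = self.data[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return float("nan")
        a = np.maximum(s[lo:hi], start)
        b = np.minimum(e[lo:hi], end)
        ov = np.clip(b - a, 0, None)
        mass = ov * v[lo:hi]
        total = np.sum(mass)
        if total <= 0:
            return float("nan")
        centers = (a + b) / 2.0
        return float(np.sum(mass * centers) / total)


class MethylomeTrack:
    """Per-CpG methylation for one sample: chrom, position, beta in [0, 1],
    read coverage. Positions are strictly increasing per chromosome.
    """

    def __init__(self, df: pd.DataFrame, sample: str | None = None):
        required = {"chrom", "pos", "beta", "coverage"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"MethylomeTrack missing columns {sorted(missing)}")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if ((df["beta"] < 0) | (df["beta"] > 1)).any():
            raise ValueError("beta outside [0, 1]")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicated CpG positions")
        self.df = df
        self.sample = sample

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def betas(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "beta"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        self.df[["chrom", "pos", "beta", "coverage"]].to_csv(path, sep="\t", header=False, index=False)


def read_methylome(path: str | Path, min_coverage: int = 5, sample: str | None = None) -> MethylomeTrack:
    """Read a bedGraph-like methylome TSV (chrom, pos, beta, coverage).

    CpGs covered by fewer than ``min_coverage`` reads are dropped — only
    sites supported by at least that many reads are trusted. Betas are
    validated to [0, 1] (tiny float excursions are clamped; anything larger
    is a data error).
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "pos", "beta", "coverage"], dtype=str)
    for col in ("pos", "beta", "coverage"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: line {line}: cannot parse {col}={raw[col][bad.idxmax()]!r}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 1
            raise ParseError(f"{path}: line {line}: missing {col}")
        raw[col] = converted
    beta = raw["beta"].to_numpy(dtype=float)
    out_of_range = (beta < -1e-9) | (beta > 1 + 1e-9)
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range)[0]) + 1
        raise ParseError(f"{path}: line {line}: beta={beta[out_of_range][0]} outside [0, 1]")
    raw["beta"] = np.clip(beta, 0.0, 1.0)
    raw["pos"] = raw["pos"].astype(np.int64)
    raw["coverage"] = raw["coverage"].astype(np.int64)
    kept = raw[raw["coverage"] >= min_coverage]
    return MethylomeTrack(kept.reset_index(drop=True), sample=sample)


def aggregate_around_anchors(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    bin_size: int,
    normalize: str = "none",
) -> np.ndarray:
    """Mean signal profile around oriented anchor points.

    Each anchor is (chrom, position, orientation) where orientation '+' means
    the feature interior lies to the right of the anchor and '-' to the left.
    The profile has 2*flank/bin_size bins; after orientation alignment, bins
    [0, n/2) are outside the feature and [n/2, n) inside. Bins with no
    covered signal at an anchor are treated as missing (excluded from the
    cross-anchor mean), so unmappable stretches do not deflate the profile.
    With ``normalize='flank_outside'`` the profile is divided by its mean
    over the outside-flank bins.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if normalize not in {"none", "flank_outside"}:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    n_bins = 2 * flank // bin_size
    rows = []
    for chrom, pos, orientation in anchors:
        vals = np.full(n_bins, np.nan)
        for k in range(n_bins):
            a = pos - flank + k * bin_size
            b = a + bin_size
            if a < 0:
                continue
            vals[k] = track.mean_in(chrom, a, b)
        if orientation == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        return np.full(n_bins, np.nan)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # all-missing bins are flagged as NaN by contract
        _warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(np.vstack(rows), axis=0)
        if normalize == "flank_outside":
            outside = profile[: n_bins // 2]
            denom = np.nanmean(outside)
            profile = profile / denom
    return profile


def nearest_distance_histogram(
    features: IntervalSet,
    anchors: Sequence[tuple[str, int]],
    max_dist: int,
    bin_size: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of signed distances from anchors to the nearest feature midpoint.

    Distance is (feature midpoint - anchor position); anchors whose nearest
    feature lies beyond max_dist (or on a chromosome with no features) fall
    into the overflow count. Returns (counts, bin_edges, overflow) with edges
    spanning [-max_dist, +max_dist] in steps of bin_size.
    """
    if max_dist % bin_size != 0:
        raise ValueError("bin_size must divide max_dist")
    edges = np.arange(-max_dist, max_dist + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    overflow = 0
    mids = features.midpoints()
    by_chrom = {str(c): np.sort(sub["pos"].to_numpy()) for c, sub in mids.groupby("chrom")}
    for chrom, pos in anchors:
        m = by_chrom.get(chrom)
        if m is None or m.size == 0:
            overflow += 1
            continue
        j = np.searchsorted(m, pos)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < m.size:
                d = int(m[cand]) - int(pos)
                if best is None or abs(d) < abs(best):
                    best = d
        if abs(best) > max_dist:
            overflow += 1
            continue
        k = min(int(np.searchsorted(edges, best, side="right")) - 1, len(counts) - 1)
        counts[k] += 1
    return counts, edges, overflow
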