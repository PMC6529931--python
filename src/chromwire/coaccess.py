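"""Single-cell ATAC co-accessibility and promoter-enhancer wiring.

Two loci that open and close together across single cells are candidates
for a regulatory link (spatial contact or shared regulation). The pipeline:
cell quality control on integration counts; enumeration of same-chromosome
promoter-enhancer pairs within TAD-sized 100-kb windows; the phi
coefficient (Pearson correlation of the two binary accessibility columns)
per pair; a calling threshold taken from the null distribution of
correlations after permuting each locus column across cells; classification
of called pairs across two conditions into disease-only (C), control-only
(H) and shared (CH); and rewired promoters — promoters wired to enhancers
in both conditions but sharing none.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, IntervalSet

__all__ = [
    "AccessibilityMatrix",
    "WiringPair",
    "qc_cells",
    "candidate_pairs",
    "pair_correlations",
    "permutation_threshold",
    "call_and_classify",
    "rewired_promoters",
]

LOCUS_ROLES = {"promoter", "enhancer"}


class AccessibilityMatrix:
    """Binary cells x loci accessibility with locus roles and cell counts.

    ``values`` is a dense uint8 matrix (scATAC locus panels here are small);
    ``loci`` is a DataFrame with chrom, start, end, role ('promoter' or
    'enhancer') and gene (promoters only); ``counts`` holds per-cell unique
    integration counts used for QC.
    """

    def __init__(self, cells: Sequence[str], loci: pd.DataFrame, values: np.ndarray,
                 counts: np.ndarray, qc_bounds: tuple[float, float] | None = None):
        values = np.asarray(values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("accessibility values must be binary")
        if values.shape != (len(cells), len(loci)):
            raise ValueError("values shape must be (n_cells, n_loci)")
        missing = {"chrom", "start", "end", "role"} - set(loci.columns)
        if missing:
            raise ValueError(f"loci table missing columns {sorted(missing)}")
        if not set(loci["role"]).issubset(LOCUS_ROLES):
            raise ValueError("locus roles must be 'promoter' or 'enhancer'")
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(cells),):
            raise ValueError("one integration count per cell required")
        order = loci.sort_values(["chrom", "start", "end"], kind="stable").index.to_numpy()
        self.cells = list(cells)
        self.loci = loci.loc[order].reset_index(drop=True)
        self.values = values.astype(np.uint8)[:, order]
        self.counts = counts
        self.qc_bounds = qc_bounds  # set once by qc_cells; not recomputed after

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_interval(self, j: int) -> GenomicInterval:
        row = self.loci.iloc[j]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))

    # -- triplet + BED + cell TSV serialization ---------------------------
    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        cell_idx, locus_idx = np.nonzero(self.values)
        pd.DataFrame({"cell": cell_idx, "locus": locus_idx, "value": 1}).to_csv(
            f"{prefix}.triplets.tsv", sep="\t", index=False)
        loci = self.loci.copy()
        if "gene" not in loci.columns:
            loci["gene"] = "."
        loci[["chrom", "start", "end", "role", "gene"]].to_csv(
            f"{prefix}.loci.bed", sep="\t", header=False, index=False)
        pd.DataFrame({"cell": self.cells, "count": self.counts}).to_csv(
            f"{prefix}.cells.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str | Path) -> "AccessibilityMatrix":
        prefix = Path(prefix)
        trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t")
        loci = pd.read_csv(f"{prefix}.loci.bed", sep="\t", header=None,
                           names=["chrom", "start", "end", "role", "gene"], dtype={"chrom": str})
        cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t")
        values = np.zeros((len(cells), len(loci)), dtype=np.uint8)
        values[trip["cell"].to_numpy(), trip["locus"].to_numpy()] = 1
        return cls(cells["cell"].astype(str).tolist(), loci, values,
                   cells["count"].to_numpy())


@dataclasses.dataclass(frozen=True)
class WiringPair:
    promoter: GenomicInterval
    enhancer: GenomicInterval
    gene: str
    correlation: float
    distance: int
    condition_class: str = "unassigned"  # C | H | CH | unassigned

    def __post_init__(self) -> None:
        if self.promoter.chrom != self.enhancer.chrom:
            raise ValueError("promoter and enhancer must share a chromosome")
        if self.condition_class not in {"C", "H", "CH", "unassigned"}:
            raise ValueError(f"bad condition class {self.condition_class!r}")


def qc_cells(m: AccessibilityMatrix, low_factor: float = 0.2, high_sds: float = 3.0) -> AccessibilityMatrix:
    """Drop cells with aberrant integration counts.

    Cells with fewer than ``low_factor`` times the mean count (likely dead or
    empty) or more than ``high_sds`` population standard deviations above the
    mean (likely doublets) are removed. Both bounds are computed once on the
    original input counts (carried on the returned matrix), never iterated,
    so repeated application is the identity.
    """
    if m.n_cells < 10:
        raise ValueError("need >= 10 cells for QC")
    if m.qc_bounds is not None:
        low, high = m.qc_bounds
    else:
        mean = float(m.counts.mean())
        sd = float(m.counts.std())  # population SD
        low = low_factor * mean
        high = mean + high_sds * sd
    keep = (m.counts >= low) & (m.counts <= high)
    if not keep.any():
        raise ValueError("QC removed all cells")
    return AccessibilityMatrix(
        [c for c, k in zip(m.cells, keep) if k],
        m.loci, m.values[keep], m.counts[keep], qc_bounds=(low, high),
    )


def candidate_pairs(loci: pd.DataFrame, max_distance: int = 100_000) -> list[tuple[int, int]]:
    """All same-chromosome (promoter_index, enhancer_index) pairs whose
    midpoints lie within ``max_distance`` bp of each other."""
    mids = ((loci["start"] + loci["end"]) // 2).to_numpy()
    chroms = loci["chrom"].to_numpy()
    roles = loci["role"].to_numpy()
    prom = np.flatnonzero(roles == "promoter")
    enh = np.flatnonzero(roles == "enhancer")
    pairs = []
    for i in prom:
        for j in enh:
            if chroms[i] == chroms[j] and abs(int(mids[i]) - int(mids[j])) <= max_distance:
                pairs.append((int(i), int(j)))
    return pairs


def _phi_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise phi for binary columns; (phi matrix, valid-column mask)."""
    x = values.astype(np.float64)
    n = x.shape[0]
    p = x.mean(axis=0)
    valid = (p > 0) & (p < 1)
    joint = (x.T @ x) / n
    denom = np.sqrt(np.outer(p * (1 - p), p * (1 - p)))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (joint - np.outer(p, p)) / denom
    return phi, valid


def pair_correlations(m: AccessibilityMatrix, pairs: Sequence[tuple[int, int]]) -> tuple[list[WiringPair], int]:
    """Phi coefficient for each candidate pair across QC-passed cells.

    Pairs touching a constant locus column (open or closed in every cell)
    have undefined correlation and are skipped; the count of skipped pairs
    is returned alongside the wired pairs (class 'unassigned').
    """
    phi, valid = _phi_matrix(m.values)
    mids = ((m.loci["start"] + m.loci["end"]) // 2).to_numpy()
    genes = m.loci["gene"].astype(str).to_numpy() if "gene" in m.loci.columns else np.full(m.n_loci, ".")
    out: list[WiringPair] = []
    skipped = 0
    for i, j in pairs:
        if not (valid[i] and valid[j]):
            skipped += 1
            continue
        out.append(WiringPair(
            promoter=m.locus_interval(i),
            enhancer=m.locus_interval(j),
            gene=str(genes[i]),
            correlation=float(phi[i, j]),
            distance=abs(int(mids[i]) - int(mids[j])),
        ))
    return out, skipped


def permutation_threshold(
    m: AccessibilityMatrix,
    pairs: Sequence[tuple[int, int]],
    n_perm: int = 100,
    quantile: float = 0.999,
    seed: int = 0,
) -> float:
    """Correlation threshold from permutation-null spurious correlations.

    Each permutation shuffles every locus column independently across cells,
    preserving per-locus open frequencies while destroying all dependence;
    the candidate-pair correlations of all permutations are pooled and the
    requested quantile returned. Deterministic given the seed.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    n = m.n_cells
    pooled = []
    pair_idx = np.asarray(pairs, dtype=np.intp)
    for _ in range(n_perm):
        perm = np.empty_like(m.values)
        for j in range(m.n_loci):
            perm[:, j] = m.values[rng.permutation(n), j]
        phi, valid = _phi_matrix(perm)
        ok = valid[pair_idx[:, 0]] & valid[pair_idx[:, 1]]
        pooled.append(phi[pair_idx[ok, 0], pair_idx[ok, 1]])
    pooled = np.concatenate(pooled)
    if quantile >= 1.0:
        return float(pooled.max())
    return float(np.quantile(pooled, quantile))


def _pairs_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _promoter_key(p: WiringPair) -> tuple:
    if p.gene and p.gene != ".":
        return ("gene", p.gene)
    return ("locus", p.promoter.chrom, p.promoter.start, p.promoter.end)


def call_and_classify(
    pairs_by_condition: Mapping[str, Sequence[WiringPair]],
    thresholds: Mapping[str, float],
    disease: str = "CLL",
    control: str = "NBC",
) -> tuple[list[WiringPair], dict[str, int]]:
    """Call pairs per condition and classify across conditions.

    A pair is called in a condition iff its correlation is at least that
    condition's threshold. A disease-called pair matches a control-called
    pair when the promoters agree (same gene, or identical locus when no
    gene id is present) and the enhancers overlap by >= 1 bp. Matched pairs
    are class CH; unmatched disease pairs are C; unmatched control pairs H.
    Each pair appears once: CH entries carry the disease-side correlation.
    Returns the classified called pairs and the class summary counts.
    """
    called = {
        cond: [p for p in pairs_by_condition.get(cond, []) if p.correlation >= thresholds[cond]]
        for cond in (disease, control)
    }
    ctrl_by_prom: dict[tuple, list[WiringPair]] = {}
    for p in called[control]:
        ctrl_by_prom.setdefault(_promoter_key(p), []).append(p)
    out: list[WiringPair] = []
    matched_ctrl: set[int] = set()
    for p in called[disease]:
        match = False
        for q in ctrl_by_prom.get(_promoter_key(p), []):
            if _pairs_overlap(p.enhancer, q.enhancer):
                match = True
                matched_ctrl.add(id(q))
        out.append(dataclasses.replace(p, condition_class="CH" if match else "C"))
    for q in called[control]:
        if id(q) not in matched_ctrl:
            out.append(dataclasses.replace(q, condition_class="H"))
    summary = {cls: sum(1 for p in out if p.condition_class == cls) for cls in ("C", "H", "CH")}
    return out, summary


def rewired_promoters(classified: Sequence[WiringPair]) -> list[tuple]:
    """Promoters wired in both conditions with disjoint enhancer repertoires.

    A promoter is rewired iff it has at least one disease-only (C) and one
    control-only (H) called pair and no shared (CH) pair.
    """
    by_prom: dict[tuple, set[str]] = {}
    for p in classified:
        by_prom.setdefault(_promoter_key(p), set()).add(p.condition_class)
    return [key for key, classes in sorted(by_prom.items())
            if {"C", "H"}.issubset(classes) and "CH" not in classes]


def pairs_to_dataframe(pairs: Sequence[WiringPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.promoter.chrom, p.promoter.start, p.promoter.end, p.gene,
             p.enhancer.chrom, p.enhancer.start, p.enhancer.end,
             p.correlation, p.distance, p.condition_class)
            for p in pairs
        ],
        columns=["prom_chrom", "prom_start", "prom_end", "gene",
                 "enh_chrom", "enh_start", "enh_end",
                 "correlation", "distance", "class"],
    )
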