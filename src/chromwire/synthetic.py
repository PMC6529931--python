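"""Seeded synthetic-data generators with planted ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — multi-sample methylomes with planted partially methylated
domains, two-group methylomes with planted DMRs and a maturation reference,
three-component log2 fold-change mixtures, stranded coverage with divergent
loci, binary single-cell accessibility with planted co-accessible pairs,
and a regulator-target network with planted deregulation. Every generator
is a pure function of its parameters and seed, and returns a PlantedTruth
sufficient to score any downstream caller.

Methylation noise is modelled as a Beta distribution parameterized by mean
and concentration: bounded in [0, 1] and matching the U-shaped-to-unimodal
marginals of bisulfite beta values.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd

from .coaccess import AccessibilityMatrix
from .genomic_io import IntervalSet, MethylomeTrack, SignalTrack

__all__ = [
    "PlantedTruth",
    "gen_methylomes",
    "gen_dmr_scenario",
    "gen_fc_mixture",
    "gen_stranded_coverage",
    "gen_scatac",
    "gen_grn",
    "maturation_map_for",
]

CHROM = "chr1"


@dataclasses.dataclass
class PlantedTruth:
    """What was planted, with the parameters that generated it."""

    scenario: str
    seed: int
    params: dict[str, Any]
    data: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _beta_draw(rng: np.random.Generator, mean: float, concentration: float, size) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


# ---------------------------------------------------------------------------
# methylomes with planted PMDs
# ---------------------------------------------------------------------------

def _place_domains(rng: np.random.Generator, genome_length: int, n: int,
                   length_range: tuple[int, int], margin: int) -> np.ndarray:
    """Non-overlapping domains separated by >= margin, spanning the genome.

    Lengths are log-uniform over the range (domain sizes span an order of
    magnitude); the leftover genome is split into inter-domain gaps by a
    Dirichlet draw so placement always succeeds when capacity allows.
    """
    lo, hi = length_range
    for _ in range(100):
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)
        if lengths.sum() + (n + 1) * margin <= genome_length:
            break
    else:
        raise ValueError("requested domains exceed genome capacity")
    free = genome_length - int(lengths.sum()) - (n + 1) * margin
    gaps = margin + (rng.dirichlet(np.ones(n + 1)) * free).astype(np.int64)
    starts = np.empty(n, dtype=np.int64)
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        starts[i] = pos
        pos += int(lengths[i])
    return np.stack([starts, starts + lengths], axis=1)


def gen_methylomes(
    n_samples: int = 11,
    genome_length: int = 20_000_000,
    cpg_spacing: int = 100,
    n_pmds: int = 15,
    pmd_length_range: tuple[int, int] = (150_000, 2_000_000),
    beta_in_mean: float = 0.45,
    beta_out_mean: float = 0.85,
    beta_concentration: float = 10.0,
    shared_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[MethylomeTrack], PlantedTruth]:
    """Multi-sample methylomes with planted partially methylated domains.

    One chromosome with a CpG every ``cpg_spacing`` bp; per-CpG betas are
    Beta-distributed with mean ``beta_in_mean`` inside planted PMDs and
    ``beta_out_mean`` outside (straddling the 0.65 calling boundary).
    ``shared_fraction`` of the PMDs appear in every sample; the rest in a
    random subset of samples (each with probability 1/2, at least one).
    Coverage is Poisson around a typical 30x WGBS depth.
    """
    if not beta_in_mean < 0.65 < beta_out_mean:
        raise ValueError("beta means must straddle the 0.65 calling boundary")
    if pmd_length_range[0] < 100_000:
        raise ValueError("planted PMDs must be at least 100 kb")
    rng = np.random.default_rng(seed)
    domains = _place_domains(rng, genome_length, n_pmds, pmd_length_range, margin=50_000) \
        if n_pmds > 0 else np.empty((0, 2), dtype=np.int64)
    n_shared = int(round(shared_fraction * n_pmds))
    membership = np.zeros((n_pmds, n_samples), dtype=bool)
    membership[:n_shared] = True
    for k in range(n_shared, n_pmds):
        row = rng.random(n_samples) < 0.5
        if not row.any():
            row[rng.integers(n_samples)] = True
        membership[k] = row
    pos = np.arange(cpg_spacing, genome_length, cpg_spacing, dtype=np.int64)
    tracks = []
    per_sample_truth = []
    for s in range(n_samples):
        inside = np.zeros(pos.size, dtype=bool)
        rows = []
        for k in range(n_pmds):
            if membership[k, s]:
                a, b = domains[k]
                inside |= (pos >= a) & (pos < b)
                rows.append((CHROM, int(a), int(b)))
        beta = np.where(inside,
                        _beta_draw(rng, beta_in_mean, beta_concentration, pos.size),
                        _beta_draw(rng, beta_out_mean, beta_concentration, pos.size))
        coverage = rng.poisson(30, size=pos.size)
        tracks.append(MethylomeTrack(
            pd.DataFrame({"chrom": CHROM, "pos": pos, "beta": beta, "coverage": coverage}),
            sample=f"sample{s}"))
        per_sample_truth.append(
            IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
            if rows else IntervalSet.empty())
    all_pmds = IntervalSet(pd.DataFrame(
        [(CHROM, int(a), int(b)) for a, b in domains], columns=["chrom", "start", "end"])) \
        if n_pmds else IntervalSet.empty()
    truth = PlantedTruth(
        scenario="methylomes", seed=seed,
        params=dict(n_samples=n_samples, genome_length=genome_length,
                    cpg_spacing=cpg_spacing, n_pmds=n_pmds,
                    pmd_length_range=pmd_length_range, beta_in_mean=beta_in_mean,
                    beta_out_mean=beta_out_mean, beta_concentration=beta_concentration,
                    shared_fraction=shared_fraction),
        data=dict(pmds=all_pmds, per_sample_pmds=per_sample_truth, membership=membership),
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# DMR scenario with maturation reference
# ---------------------------------------------------------------------------

def gen_dmr_scenario(
    n_per_group: int = 6,
    n_dmrs: int = 30,
    delta: float = 0.4,
    maturation_overlap_fraction: float = 0.3,
    genome_length: int = 2_000_000,
    background_spacing: int = 200,
    dmr_spacing: int = 25,
    dmr_length_range: tuple[int, int] = (400, 800),
    background_beta: float = 0.75,
    beta_concentration: float = 30.0,
    seed: int = 0,
) -> tuple[list[MethylomeTrack], list[MethylomeTrack], pd.DataFrame, PlantedTruth]:
    """Two-group methylomes with planted hypomethylated DMRs.

    Group 1 (disease) loses ``delta`` beta inside each planted region; CpGs
    are dense (every ``dmr_spacing`` bp) inside DMRs, sparse outside. A
    ``maturation_overlap_fraction`` of the planted DMRs also shift by the
    same delta in the maturation reference (memory vs naive B cells),
    making them filterable; the returned maturation table carries one row
    per planted region with its maturation delta.
    """
    if delta < 0.3:
        raise ValueError("planted-true DMRs need delta >= 0.3")
    rng = np.random.default_rng(seed)
    regions = _place_domains(rng, genome_length, n_dmrs, dmr_length_range, margin=5_000)
    n_filterable = int(round(maturation_overlap_fraction * n_dmrs))
    filterable = np.zeros(n_dmrs, dtype=bool)
    filterable[rng.permutation(n_dmrs)[:n_filterable]] = True

    pos_parts = [np.arange(background_spacing, genome_length, background_spacing, dtype=np.int64)]
    for a, b in regions:
        pos_parts.append(np.arange(a, b, dmr_spacing, dtype=np.int64))
    pos = np.unique(np.concatenate(pos_parts))
    in_dmr = np.zeros(pos.size, dtype=bool)
    for a, b in regions:
        in_dmr |= (pos >= a) & (pos < b)

    def make_group(shift_inside: float, n: int, label: str) -> list[MethylomeTrack]:
        tracks = []
        for s in range(n):
            mean = np.where(in_dmr, background_beta + shift_inside, background_beta)
            k = beta_concentration
            beta = rng.beta(mean * k, (1 - mean) * k)
            coverage = rng.poisson(30, size=pos.size)
            tracks.append(MethylomeTrack(
                pd.DataFrame({"chrom": CHROM, "pos": pos, "beta": beta, "coverage": coverage}),
                sample=f"{label}{s}"))
        return tracks

    group1 = make_group(-delta, n_per_group, "g1_")
    group2 = make_group(0.0, n_per_group, "g2_")
    maturation = pd.DataFrame({
        "chrom": CHROM,
        "start": regions[:, 0],
        "end": regions[:, 1],
        "mat_delta": np.where(filterable, -delta, 0.0),
    })
    truth = PlantedTruth(
        scenario="dmr", seed=seed,
        params=dict(n_per_group=n_per_group, n_dmrs=n_dmrs, delta=delta,
                    maturation_overlap_fraction=maturation_overlap_fraction,
                    genome_length=genome_length),
        data=dict(
            dmrs=IntervalSet(pd.DataFrame(
                [(CHROM, int(a), int(b)) for a, b in regions],
                columns=["chrom", "start", "end"])),
            filterable=filterable,
            maturation=maturation,
        ),
    )
    return group1, group2, maturation, truth


def maturation_map_for(dmrs, maturation: pd.DataFrame) -> dict[tuple[str, int, int], float]:
    """Region-level maturation deltas for called DMRs.

    Each called DMR gets the maturation delta of the reference region it
    overlaps (0 if none), keyed the way maturation_filter expects.
    """
    out = {}
    for d in dmrs:
        iv = d.interval
        hit = maturation[(maturation["chrom"] == iv.chrom)
                         & (maturation["start"] < iv.end)
                         & (maturation["end"] > iv.start)]
        out[(iv.chrom, iv.start, iv.end)] = float(hit["mat_delta"].iloc[0]) if len(hit) else 0.0
    return out


# ---------------------------------------------------------------------------
# fold-change mixture
# ---------------------------------------------------------------------------

def gen_fc_mixture(
    weights: tuple[float, float, float] = (0.25, 0.5, 0.25),
    means: tuple[float, float, float] = (-2.0, 0.0, 2.0),
    sds: tuple[float, float, float] = (0.5, 1.0, 0.5),
    n: int = 50_000,
    seed: int = 0,
) -> tuple[np.ndarray, PlantedTruth]:
    """Log2 fold changes from a three-component Gaussian mixture
    (down-regulated / null / up-regulated). Truth records the parameters and
    the analytic crossover thresholds of the true mixture."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if np.any(np.asarray(sds) <= 0):
        raise ValueError("sds must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=w)
    values = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
    from .diffthreshold import MixtureFit, crossover_points
    order = np.argsort(means)
    true_fit = MixtureFit(weights=w[order], means=np.asarray(means, dtype=float)[order],
                          sds=np.asarray(sds, dtype=float)[order],
                          loglik=float("nan"), n_iter=0, converged=True)
    crossovers = crossover_points(true_fit) if np.all(w[order][:2] > 0) and np.all(w[order][1:] > 0) else None
    truth = PlantedTruth(
        scenario="fc_mixture", seed=seed,
        params=dict(weights=tuple(weights), means=tuple(means), sds=tuple(sds), n=n),
        data=dict(components=comp, crossovers=crossovers),
    )
    return values, truth


# ---------------------------------------------------------------------------
# stranded coverage with divergent loci
# ---------------------------------------------------------------------------

def gen_stranded_coverage(
    n_bidi: int = 30,
    n_unidirectional: int = 30,
    window: int = 1000,
    minor_ratio: float = 0.6,
    n_excluded_exonic: int = 5,
    n_excluded_tss: int = 3,
    major_reads: float = 100.0,
    locus_spacing: int = 5_000,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack, dict[str, IntervalSet], PlantedTruth]:
    """Stranded coverage with planted divergent (eRNA-like) loci.

    Bidirectional loci place minus-strand mass 5' (left) of the plus-strand
    mass inside the window, with the minor strand carrying ``minor_ratio``
    of the major strand's reads (well above the 20% calling rule).
    Unidirectional loci carry < 10% minor-strand mass co-located with the
    major strand. Additional divergent loci are planted overlapping exons
    on both strands or a TSS; the truth records them as excluded.
    """
    rng = np.random.default_rng(seed)
    order = ["bidi"] * n_bidi + ["uni"] * n_unidirectional \
        + ["exonic"] * n_excluded_exonic + ["tss"] * n_excluded_tss
    order = [order[i] for i in rng.permutation(len(order))]
    half = window // 2
    plus_iv, minus_iv = [], []
    bidi_centers, uni_centers, excl_exonic, excl_tss = [], [], [], []
    tss_rows, exp_rows, exm_rows = [], [], []
    pos = locus_spacing
    for kind in order:
        c = pos
        if kind in ("bidi", "exonic", "tss"):
            span = int(0.3 * half)  # each strand's block, on its own side
            minor = minor_ratio * (1 + rng.uniform(-0.05, 0.05))
            minus_iv.append((c - int(0.8 * half), c - int(0.8 * half) + span,
                             major_reads * minor / span))
            plus_iv.append((c + int(0.8 * half) - span, c + int(0.8 * half),
                            major_reads / span))
            if kind == "bidi":
                bidi_centers.append(c)
            elif kind == "exonic":
                excl_exonic.append(c)
                exp_rows.append((CHROM, c - half, c + half))
                exm_rows.append((CHROM, c - half, c + half))
            else:
                excl_tss.append(c)
                tss_rows.append((CHROM, c - 50, c + 50))
        else:  # unidirectional: plus-dominant, minor mass co-located and tiny
            span = int(0.3 * half)
            plus_iv.append((c + 100, c + 100 + span, major_reads / span))
            minus_iv.append((c + 100, c + 100 + span, 0.05 * major_reads / span))
            uni_centers.append(c)
        pos += locus_spacing
    plus = SignalTrack()
    minus = SignalTrack()
    for track, ivs in ((plus, plus_iv), (minus, minus_iv)):
        ivs = sorted(ivs)
        track.add_chrom(CHROM,
                        [a for a, _, _ in ivs], [b for _, b, _ in ivs], [v for _, _, v in ivs])
    annotations = {
        "tss": IntervalSet(pd.DataFrame(tss_rows, columns=["chrom", "start", "end"]))
        if tss_rows else IntervalSet.empty(),
        "exons_plus": IntervalSet(pd.DataFrame(exp_rows, columns=["chrom", "start", "end"]))
        if exp_rows else IntervalSet.empty(),
        "exons_minus": IntervalSet(pd.DataFrame(exm_rows, columns=["chrom", "start", "end"]))
        if exm_rows else IntervalSet.empty(),
    }
    truth = PlantedTruth(
        scenario="stranded", seed=seed,
        params=dict(n_bidi=n_bidi, n_unidirectional=n_unidirectional, window=window,
                    minor_ratio=minor_ratio, major_reads=major_reads),
        data=dict(bidi_centers=bidi_centers, uni_centers=uni_centers,
                  excluded_exonic=excl_exonic, excluded_tss=excl_tss),
    )
    return plus, minus, annotations, truth


# ---------------------------------------------------------------------------
# single-cell ATAC with planted co-accessible pairs
# ---------------------------------------------------------------------------

def true_pair_phi(baseline_rate: float, co_open_boost: float, latent_rate: float = 0.5) -> float:
    """Analytic phi of a linked pair under the shared-latent-factor model."""
    p1 = min(baseline_rate + co_open_boost, 0.95)
    p = latent_rate * p1 + (1 - latent_rate) * baseline_rate
    e_xy = latent_rate * p1**2 + (1 - latent_rate) * baseline_rate**2
    return (e_xy - p * p) / (p * (1 - p))


def gen_scatac(
    n_cells_per_condition: int = 500,
    n_promoters: int = 30,
    n_enhancers: int = 60,
    baseline_rate: float = 0.1,
    n_linked_pairs: int = 10,
    co_open_boost: float = 0.6,
    n_rewired: int = 5,
    max_pair_distance: int = 80_000,
    n_qc_low: int = 2,
    n_qc_high: int = 2,
    seed: int = 0,
) -> tuple[dict[str, AccessibilityMatrix], pd.DataFrame, PlantedTruth]:
    """Two-condition binary scATAC matrices with planted wiring.

    Loci sit in isolated neighborhoods (one promoter plus two enhancers
    within ``max_pair_distance``; neighborhoods farther apart than the
    100-kb pairing window). Unlinked loci open independently with
    Bernoulli(baseline_rate). A linked pair shares a per-cell latent factor:
    when it fires (probability 1/2) both loci open with probability
    baseline_rate + co_open_boost. ``n_linked_pairs`` promoters are linked
    to the same enhancer in both conditions (shared wiring); ``n_rewired``
    promoters are linked to their first enhancer in the disease condition
    and their second in the control (rewired). A few cells with extreme
    integration counts are planted to exercise QC.
    """
    if max_pair_distance > 100_000:
        raise ValueError("planted pairs must fall inside the 100-kb pairing window")
    if n_enhancers != 2 * n_promoters:
        raise ValueError("layout uses two enhancers per promoter neighborhood")
    if n_linked_pairs + n_rewired > n_promoters:
        raise ValueError("more linked/rewired promoters than promoters")
    rng = np.random.default_rng(seed)
    spacing = 300_000
    rows = []
    for i in range(n_promoters):
        base = i * spacing
        rows.append((CHROM, base + 1_000, base + 2_000, "promoter", f"G{i}"))
        rows.append((CHROM, base + 1_500 + max_pair_distance // 2,
                     base + 2_000 + max_pair_distance // 2, "enhancer", "."))
        rows.append((CHROM, base + 1_500 + max_pair_distance - 1_000,
                     base + 2_000 + max_pair_distance - 1_000, "enhancer", "."))
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "role", "gene"])
    prom_idx = loci.index[loci["role"] == "promoter"].to_numpy()
    enh_idx = {p: loci.index[(loci["role"] == "enhancer")
                             & (loci["start"] > loci.loc[p, "start"])
                             & (loci["start"] < loci.loc[p, "start"] + spacing)].to_numpy()
               for p in prom_idx}
    chosen = rng.permutation(n_promoters)
    shared_proms = chosen[:n_linked_pairs]
    rewired_proms = chosen[n_linked_pairs:n_linked_pairs + n_rewired]

    links = {"CLL": [], "NBC": []}
    for i in shared_proms:
        p = prom_idx[i]
        e = enh_idx[p][0]
        links["CLL"].append((p, e))
        links["NBC"].append((p, e))
    for i in rewired_proms:
        p = prom_idx[i]
        links["CLL"].append((p, enh_idx[p][0]))
        links["NBC"].append((p, enh_idx[p][1]))

    p_boost = min(baseline_rate + co_open_boost, 0.95)
    matrices = {}
    qc_fail = {}
    for cond in ("CLL", "NBC"):
        n_cells = n_cells_per_condition
        values = (rng.random((n_cells, len(loci))) < baseline_rate).astype(np.uint8)
        for p, e in links[cond]:
            z = rng.random(n_cells) < 0.5
            open_p = np.where(z, p_boost, baseline_rate)
            values[:, p] = rng.random(n_cells) < open_p
            values[:, e] = rng.random(n_cells) < np.where(z, p_boost, baseline_rate)
        counts = rng.normal(70_000, 8_000, size=n_cells)
        fail = []
        for k in range(n_qc_low):
            counts[k] = 5_000
            fail.append(k)
        for k in range(n_qc_low, n_qc_low + n_qc_high):
            counts[k] = 200_000
            fail.append(k)
        cells = [f"{cond}_cell{j}" for j in range(n_cells)]
        matrices[cond] = AccessibilityMatrix(cells, loci, values, counts)
        qc_fail[cond] = [cells[k] for k in fail]

    truth = PlantedTruth(
        scenario="scatac", seed=seed,
        params=dict(n_cells_per_condition=n_cells_per_condition,
                    n_promoters=n_promoters, n_enhancers=n_enhancers,
                    baseline_rate=baseline_rate, n_linked_pairs=n_linked_pairs,
                    co_open_boost=co_open_boost, n_rewired=n_rewired,
                    max_pair_distance=max_pair_distance,
                    true_phi=true_pair_phi(baseline_rate, co_open_boost)),
        data=dict(links=links,
                  rewired_genes=[f"G{i}" for i in sorted(rewired_proms)],
                  shared_genes=[f"G{i}" for i in sorted(shared_proms)],
                  qc_fail_cells=qc_fail),
    )
    return matrices, loci, truth


# ---------------------------------------------------------------------------
# regulator-target network with planted deregulation
# ---------------------------------------------------------------------------

def gen_grn(
    n_regulators: int = 40,
    targets_per_regulator: int = 50,
    n_deregulated: int = 8,
    lfc_magnitude: float = 2.0,
    n_samples_per_group: int = 10,
    deregulated_targets_per_regulator: int = 5,
    expression_sd: float = 0.25,
    activity_shift: float = 1.5,
    activity_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Regulator-target edge list with expression, activity and DE tables.

    ``n_deregulated`` regulators get a between-group activity shift (picked
    up by the two-sided t-test / BH selection); for each, a handful of its
    targets get a between-group expression shift of ``lfc_magnitude`` log2
    units (clearing the P < 0.01, |LFC| > 1.7 gate at the stated group
    size). Returns (edges, expression, activity, regulator DE table, gene
    DE table, truth). Target counts per regulator follow the tens-of-genes
    regulon scale typical of B-cell networks.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    n_targets_pool = max(3 * targets_per_regulator, n_regulators * targets_per_regulator // 3)
    regulators = [f"R{i}" for i in range(n_regulators)]
    pool = np.array([f"T{i}" for i in range(n_targets_pool)])
    edges = []
    regulons = {}
    for r in regulators:
        tgt = rng.choice(pool, size=targets_per_regulator, replace=False)
        regulons[r] = list(tgt)
        edges.extend((r, t) for t in tgt)
    edges = pd.DataFrame(edges, columns=["regulator", "target"])

    dereg_regs = list(rng.choice(regulators, size=n_deregulated, replace=False))
    dereg_targets = []
    for r in dereg_regs:
        k = min(deregulated_targets_per_regulator, len(regulons[r]))
        dereg_targets.extend(rng.choice(regulons[r], size=k, replace=False))
    dereg_targets = sorted(set(dereg_targets))

    n1 = n2 = n_samples_per_group
    samples = [f"CLL{j}" for j in range(n1)] + [f"NBC{j}" for j in range(n2)]

    genes = sorted(set(edges["target"]))
    base = rng.normal(8.0, 1.0, size=len(genes))
    expr = rng.normal(base[:, None], expression_sd, size=(len(genes), n1 + n2))
    gene_index = {g: i for i, g in enumerate(genes)}
    signs = {}
    for g in dereg_targets:
        sign = rng.choice([-1.0, 1.0])
        signs[g] = sign
        expr[gene_index[g], :n1] += sign * lfc_magnitude
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    act = rng.normal(0.0, activity_sd, size=(n_regulators, n1 + n2))
    for r in dereg_regs:
        act[regulators.index(r), :n1] += activity_shift
    activity = pd.DataFrame(act, index=regulators, columns=samples)

    t, p = sps.ttest_ind(act[:, :n1], act[:, n1:], axis=1)
    reg_table = pd.DataFrame({"t": t, "p": p}, index=regulators)

    lfc = expr[:, :n1].mean(axis=1) - expr[:, n1:].mean(axis=1)
    t, p = sps.ttest_ind(expr[:, :n1], expr[:, n1:], axis=1)
    de_table = pd.DataFrame({"lfc": lfc, "p": p}, index=genes)

    truth = PlantedTruth(
        scenario="grn", seed=seed,
        params=dict(n_regulators=n_regulators, targets_per_regulator=targets_per_regulator,
                    n_deregulated=n_deregulated, lfc_magnitude=lfc_magnitude,
                    n_samples_per_group=n_samples_per_group),
        data=dict(deregulated_regulators=sorted(dereg_regs),
                  deregulated_targets=dereg_targets, lfc_signs=signs),
    )
    return edges, expression, activity, reg_table, de_table, truth
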