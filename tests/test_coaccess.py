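"""scATAC co-accessibility: QC, phi correlations, permutation threshold,
cross-condition classification, rewired promoters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromwire.coaccess import (
    AccessibilityMatrix,
    WiringPair,
    call_and_classify,
    candidate_pairs,
    pair_correlations,
    permutation_threshold,
    qc_cells,
    rewired_promoters,
)
from chromwire.genomic_io import GenomicInterval


def matrix(values, counts=None, roles=None):
    values = np.asarray(values)
    n_cells, n_loci = values.shape
    roles = roles or ["promoter" if j % 2 == 0 else "enhancer" for j in range(n_loci)]
    loci = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_loci) * 10_000,
        "end": np.arange(n_loci) * 10_000 + 500,
        "role": roles,
        "gene": [f"G{j}" if r == "promoter" else "." for j, r in enumerate(roles)],
    })
    counts = np.full(n_cells, 100.0) if counts is None else np.asarray(counts, float)
    return AccessibilityMatrix([f"c{i}" for i in range(n_cells)], loci, values, counts)


class TestQcCells:
    def test_hand_examples_with_ten_cells(self):
        # the two hand-computable 5-cell examples (bounds 1.64 and 136),
        # padded to the 10-cell QC minimum by duplication, which preserves
        # the mean and the population SD and hence both bounds
        counts = [10, 10, 10, 10, 1] * 2
        assert 0.2 * np.mean(counts) == pytest.approx(1.64)
        m = matrix(np.zeros((10, 2), dtype=int), counts=counts)
        out = qc_cells(m)
        assert out.n_cells == 8 and 1 not in out.counts

        counts = [10, 10, 10, 10, 100] * 2
        mean, sd = np.mean(counts), np.std(counts)
        assert (mean, sd) == (28, 36)
        assert mean + 3 * sd == 136
        out = qc_cells(matrix(np.zeros((10, 2), dtype=int), counts=counts))
        assert out.n_cells == 10  # 100 < 136: nothing removed

    def test_equal_counts_no_removal(self):
        out = qc_cells(matrix(np.zeros((12, 2), dtype=int)))
        assert out.n_cells == 12

    def test_idempotent_with_fixed_bounds(self, scatac_scenario):
        mats, _, _ = scatac_scenario
        once = qc_cells(mats["CLL"])
        twice = qc_cells(once)
        assert twice.cells == once.cells

    def test_all_removed_is_error(self):
        m = matrix(np.zeros((10, 2), dtype=int))
        with pytest.raises(ValueError, match="all cells"):
            qc_cells(m, low_factor=2.0)  # bound above every equal count


class TestCandidatePairs:
    def test_distance_window(self):
        loci = pd.DataFrame({
            "chrom": "chr1",
            "start": [0, 50_000, 150_000],
            "end": [500, 50_500, 150_500],
            "role": ["promoter", "enhancer", "enhancer"],
        })
        assert candidate_pairs(loci) == [(0, 1)]

    def test_same_role_pairs_excluded(self):
        loci = pd.DataFrame({
            "chrom": "chr1", "start": [0, 1000], "end": [500, 1500],
            "role": ["promoter", "promoter"]})
        assert candidate_pairs(loci) == []

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(41)
        n = 30
        loci = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n),
            "start": rng.integers(0, 400_000, n),
            "role": rng.choice(["promoter", "enhancer"], n),
        })
        loci["end"] = loci["start"] + 500
        got = set(candidate_pairs(loci))
        mids = (loci["start"] + loci["end"]) // 2
        expected = {
            (i, j)
            for i, j in itertools.product(range(n), range(n))
            if loci["role"][i] == "promoter" and loci["role"][j] == "enhancer"
            and loci["chrom"][i] == loci["chrom"][j]
            and abs(int(mids[i]) - int(mids[j])) <= 100_000
        }
        assert got == expected


class TestPairCorrelations:
    def test_identical_columns_phi_one(self):
        col = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        m = matrix(np.stack([col, col], axis=1))
        out, skipped = pair_correlations(m, [(0, 1)])
        assert skipped == 0
        assert out[0].correlation == pytest.approx(1.0)

    def test_hand_2x2_table_phi(self):
        # n11=40, n10=10, n01=10, n00=40 -> phi = 0.6
        a = np.array([1] * 50 + [0] * 50)
        b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        m = matrix(np.stack([a, b], axis=1))
        out, _ = pair_correlations(m, [(0, 1)])
        assert out[0].correlation == pytest.approx(0.6)

    def test_constant_column_skipped_with_count(self):
        a = np.ones(20, dtype=int)
        b = np.tile([0, 1], 10)
        m = matrix(np.stack([a, b], axis=1))
        out, skipped = pair_correlations(m, [(0, 1)])
        assert out == [] and skipped == 1

    def test_independent_columns_small_phi(self):
        rng = np.random.default_rng(43)
        m = matrix((rng.random((1000, 2)) < 0.3).astype(int))
        out, _ = pair_correlations(m, [(0, 1)])
        assert abs(out[0].correlation) <= 0.1

    def test_phi_symmetric_and_cell_order_invariant(self):
        rng = np.random.default_rng(44)
        vals = (rng.random((200, 2)) < 0.4).astype(int)
        m = matrix(vals)
        fwd, _ = pair_correlations(m, [(0, 1)])
        perm = rng.permutation(200)
        m2 = AccessibilityMatrix([m.cells[i] for i in perm], m.loci,
                                 m.values[perm], m.counts[perm])
        rev, _ = pair_correlations(m2, [(0, 1)])
        assert fwd[0].correlation == pytest.approx(rev[0].correlation)


class TestPermutationThreshold:
    def test_quantile_one_is_pooled_max(self):
        rng = np.random.default_rng(45)
        m = matrix((rng.random((100, 4)) < 0.3).astype(int))
        pairs = candidate_pairs(m.loci)
        t_max = permutation_threshold(m, pairs, n_perm=10, quantile=1.0, seed=1)
        t_q = permutation_threshold(m, pairs, n_perm=10, quantile=0.9, seed=1)
        assert t_q <= t_max

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(46)
        m = matrix((rng.random((100, 4)) < 0.3).astype(int))
        pairs = candidate_pairs(m.loci)
        assert permutation_threshold(m, pairs, seed=7) == \
            permutation_threshold(m, pairs, seed=7)

    def test_null_matrix_false_call_rate_controlled(self):
        rng = np.random.default_rng(47)
        m = matrix((rng.random((500, 40)) < 0.2).astype(int))
        pairs = candidate_pairs(m.loci)
        thr = permutation_threshold(m, pairs, n_perm=50, quantile=0.999, seed=2)
        wired, _ = pair_correlations(m, pairs)
        frac = np.mean([p.correlation >= thr for p in wired])
        n = len(wired)
        assert frac <= 0.001 + 3 * np.sqrt(0.001 * 0.999 / n) + 1 / n


def wp(gene, enh_start, corr, cls="unassigned"):
    return WiringPair(GenomicInterval("chr1", 0, 500),
                      GenomicInterval("chr1", enh_start, enh_start + 500),
                      gene, corr, enh_start, cls)


class TestCallAndClassify:
    def test_shared_pair_is_ch(self):
        out, summary = call_and_classify(
            {"CLL": [wp("G1", 10_000, 0.5)], "NBC": [wp("G1", 10_000, 0.4)]},
            {"CLL": 0.22, "NBC": 0.22})
        assert summary == {"C": 0, "H": 0, "CH": 1}

    def test_disease_only_pair_is_c(self):
        out, summary = call_and_classify(
            {"CLL": [wp("G1", 10_000, 0.5)], "NBC": [wp("G1", 10_000, 0.1)]},
            {"CLL": 0.22, "NBC": 0.22})
        assert summary == {"C": 1, "H": 0, "CH": 0}

    def test_six_pair_instance_matches_brute_force(self):
        cll = [wp("G1", 10_000, 0.5), wp("G1", 30_000, 0.3), wp("G2", 50_000, 0.1),
               wp("G3", 70_000, 0.4)]
        nbc = [wp("G1", 10_200, 0.45), wp("G2", 50_000, 0.6), wp("G3", 90_000, 0.5)]
        thr = {"CLL": 0.22, "NBC": 0.22}
        out, summary = call_and_classify({"CLL": cll, "NBC": nbc}, thr)
        # brute force: called CLL = G1/10k, G1/30k, G3/70k; called NBC = G1/10.2k,
        # G2/50k, G3/90k. G1 10k overlaps 10.2k -> CH; G1/30k C; G3 enhancers
        # disjoint -> C and H; G2 CLL side below threshold -> H only.
        got = {(p.gene, p.enhancer.start, p.condition_class) for p in out}
        assert got == {("G1", 10_000, "CH"), ("G1", 30_000, "C"),
                       ("G3", 70_000, "C"), ("G2", 50_000, "H"),
                       ("G3", 90_000, "H")}
        assert summary == {"C": 2, "H": 2, "CH": 1}


class TestRewiredPromoters:
    def test_c_and_h_without_ch_is_rewired(self):
        pairs = [wp("G1", 10_000, 0.5, "C"), wp("G1", 30_000, 0.5, "H")]
        assert rewired_promoters(pairs) == [("gene", "G1")]

    def test_any_shared_enhancer_disqualifies(self):
        pairs = [wp("G1", 10_000, 0.5, "C"), wp("G1", 30_000, 0.5, "H"),
                 wp("G1", 50_000, 0.5, "CH")]
        assert rewired_promoters(pairs) == []

    def test_random_instances_match_set_logic_oracle(self):
        rng = np.random.default_rng(48)
        for _ in range(20):
            pairs = [wp(f"G{rng.integers(4)}", int(e) * 1000, 0.5,
                        str(rng.choice(["C", "H", "CH"])))
                     for e in rng.integers(10, 100, size=8)]
            got = {k[1] for k in rewired_promoters(pairs)}
            by_gene = {}
            for p in pairs:
                by_gene.setdefault(p.gene, set()).add(p.condition_class)
            expected = {g for g, cls in by_gene.items()
                        if "C" in cls and "H" in cls and "CH" not in cls}
            assert got == expected


class TestEndToEndRecovery:
    def test_planted_links_and_rewiring_recovered(self, scatac_scenario):
        mats, loci, truth = scatac_scenario
        pairs_by_cond, thresholds = {}, {}
        for cond, m0 in mats.items():
            m = qc_cells(m0)
            pairs = candidate_pairs(m.loci)
            wired, _ = pair_correlations(m, pairs)
            thresholds[cond] = permutation_threshold(m, pairs, n_perm=30, seed=11)
            pairs_by_cond[cond] = wired
        classified, summary = call_and_classify(pairs_by_cond, thresholds)
        called_genes = {p.gene for p in classified}
        linked = set(truth["shared_genes"]) | set(truth["rewired_genes"])
        assert len(called_genes & linked) / len(linked) >= 0.8
        got_rewired = {k[1] for k in rewired_promoters(classified)}
        planted = set(truth["rewired_genes"])
        assert len(got_rewired & planted) / len(planted) >= 0.8
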