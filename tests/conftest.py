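import numpy as np
import pandas as pd
import pytest

from chromwire import synthetic
from chromwire.genomic_io import IntervalSet


# ---------------------------------------------------------------------------
# brute-force base-level oracles shared across modules
# ---------------------------------------------------------------------------

def base_occupancy(sets, genome_length):
    """Per-base count of how many interval sets cover each base (one chrom)."""
    occ = np.zeros(genome_length, dtype=int)
    for s in sets:
        cover = np.zeros(genome_length, dtype=bool)
        for row in s.df.itertuples(index=False):
            cover[row.start:row.end] = True
        occ += cover
    return occ


def runs_from_mask(mask):
    """(start, end) runs of True in a boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def intervalset_from_mask(mask, chrom="chr1"):
    rows = [(chrom, a, b) for a, b in runs_from_mask(mask)]
    if not rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def base_recall_precision(called, truth, genome_length):
    """Base-level recall and precision of a called set against planted truth."""
    c = base_occupancy([called], genome_length) > 0
    t = base_occupancy([truth], genome_length) > 0
    inter = (c & t).sum()
    recall = inter / t.sum() if t.sum() else float("nan")
    precision = inter / c.sum() if c.sum() else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# shared generated scenarios (session-scoped: generators are pure in seed)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def methylome_scenario():
    return synthetic.gen_methylomes(seed=1)


@pytest.fixture(scope="session")
def dmr_scenario():
    return synthetic.gen_dmr_scenario(seed=2)


@pytest.fixture(scope="session")
def mixture_scenario():
    return synthetic.gen_fc_mixture(seed=4)


@pytest.fixture(scope="session")
def stranded_scenario():
    return synthetic.gen_stranded_coverage(seed=5)


@pytest.fixture(scope="session")
def scatac_scenario():
    return synthetic.gen_scatac(seed=3)


@pytest.fixture(scope="session")
def grn_scenario():
    return synthetic.gen_grn(seed=6)
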