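"""Gene-regulatory enhancer network (GREN) assembly.

A GREN augments a regulator -> target-gene network with enhancer nodes
wired to their target genes by co-accessibility. Classified promoter-
enhancer pairs are deduplicated (overlapping enhancer regions merged across
conditions), the merged enhancers are numbered consecutively within each
condition class (C1, C2, ... / H1, ... / CH1, ...), differential selections
pick the regulators and genes of interest, and a disease subnetwork is
extracted around a set of core transcription factors.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

from .coaccess import WiringPair
from .genomic_io import IntervalSet, merge_intervals

__all__ = [
    "Selections",
    "dedup_enhancers",
    "number_enhancers",
    "select_differential_regulators",
    "select_deregulated_genes",
    "assemble_gren",
    "extract_disease_subnetwork",
    "write_graph",
    "read_graph",
]


@dataclasses.dataclass
class Selections:
    """Gene/regulator selections feeding network assembly."""

    differential_regulators: set[str] = dataclasses.field(default_factory=set)
    deregulated_genes: set[str] = dataclasses.field(default_factory=set)
    modifiers: set[str] = dataclasses.field(default_factory=set)


def dedup_enhancers(
    pairs: Sequence[WiringPair],
    promoter_gene_map: Mapping[tuple[str, int, int], str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Merge duplicate enhancer regions across conditions and remap pairs.

    Overlapping enhancer intervals (from any condition class) are merged
    into one region. A merged region is class CH if the pairs it subsumes
    include shared pairs or called pairs from both conditions; otherwise it
    keeps the single contributing class. Promoters are resolved to gene
    symbols — from the pair's own gene id or, failing that, the provided
    promoter -> gene map; pairs whose promoter cannot be mapped are dropped
    and counted. Returns (enhancer table [chrom, start, end, class],
    remapped pair table [enhancer_idx, gene, class], n_dropped). Idempotent:
    re-running on already-merged regions changes nothing.
    """
    promoter_gene_map = promoter_gene_map or {}
    rows, genes, classes = [], [], []
    n_dropped = 0
    for p in pairs:
        if p.condition_class == "unassigned":
            raise ValueError("pairs must be classified before deduplication")
        gene = p.gene if p.gene and p.gene != "." else promoter_gene_map.get(
            (p.promoter.chrom, p.promoter.start, p.promoter.end))
        if not gene:
            n_dropped += 1
            continue
        rows.append((p.enhancer.chrom, p.enhancer.start, p.enhancer.end))
        genes.append(gene)
        classes.append(p.condition_class)
    if not rows:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "class"])
        return empty, pd.DataFrame(columns=["enhancer_idx", "gene", "class"]), n_dropped
    raw = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    merged = merge_intervals(IntervalSet(raw)).df
    # map each pair's enhancer to its merged region
    enh_idx = np.full(len(raw), -1)
    for k, mrow in merged.iterrows():
        hit = ((raw["chrom"] == mrow["chrom"]) & (raw["start"] < mrow["end"])
               & (raw["end"] > mrow["start"]))
        enh_idx[hit.to_numpy()] = k
    pair_table = pd.DataFrame({"enhancer_idx": enh_idx, "gene": genes, "class": classes})
    region_class = []
    for k in range(len(merged)):
        sub = set(pair_table.loc[pair_table["enhancer_idx"] == k, "class"])
        if "CH" in sub or {"C", "H"}.issubset(sub):
            region_class.append("CH")
        else:
            region_class.append(sub.pop())
    merged = merged.assign(**{"class": region_class})
    return merged, pair_table, n_dropped


def number_enhancers(merged: pd.DataFrame) -> pd.DataFrame:
    """Assign class-prefixed serial ids in genomic order.

    Within each class, regions are numbered from 1 following (chrom, start)
    order; ids are independent of input row order. Returns the table with an
    ``id`` column (e.g. C1, C2, ..., H1, ..., CH1, ...).
    """
    out = merged.copy()
    out["id"] = ""
    for cls, sub in out.groupby("class"):
        ordered = sub.sort_values(["chrom", "start", "end"], kind="stable")
        for serial, idx in enumerate(ordered.index, start=1):
            out.loc[idx, "id"] = f"{cls}{serial}"
    return out


def select_differential_regulators(table: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Regulators with adjusted P < alpha (strict) for differential activity.

    The table is indexed by regulator with columns ``p`` and optionally
    ``p_adj``; Benjamini-Hochberg adjustment is applied when ``p_adj`` is
    absent.
    """
    if "p_adj" in table.columns:
        padj = table["p_adj"]
    else:
        from statsmodels.stats.multitest import multipletests
        padj = pd.Series(multipletests(table["p"], method="fdr_bh")[1], index=table.index)
    return set(table.index[padj < alpha].astype(str))


def select_deregulated_genes(table: pd.DataFrame, alpha: float = 0.01,
                             min_abs_lfc: float = 1.7) -> set[str]:
    """Non-regulator genes with P < alpha and |log2 fold change| > min_abs_lfc
    (both strict)."""
    sel = (table["p"] < alpha) & (table["lfc"].abs() > min_abs_lfc)
    return set(table.index[sel].astype(str))


def assemble_gren(
    grn_edges: pd.DataFrame,
    enhancers: pd.DataFrame,
    pair_table: pd.DataFrame,
    selections: Selections,
    modifier_list: Set[str] = frozenset(),
) -> tuple[nx.DiGraph, int]:
    """Build the GREN graph.

    Nodes are regulators and target genes from the edge list (regulator,
    target columns) plus numbered enhancer regions; directed regulator ->
    gene edges carry kind='regulates', and enhancer -> gene edges (from the
    deduplicated pair table) kind='enhances'. Node attributes record kind,
    differential/deregulated flags, the chromatin-modifier flag, and for
    enhancers the class and genomic position. Enhancer links to genes absent
    from the network are dropped; their count is returned.
    """
    if "id" not in enhancers.columns:
        raise ValueError("enhancers must be numbered first (missing 'id' column)")
    g = nx.DiGraph()
    regulators = set(grn_edges["regulator"].astype(str))
    genes = set(grn_edges["target"].astype(str)) | regulators
    for node in sorted(genes):
        g.add_node(node,
                   kind="regulator" if node in regulators else "target_gene",
                   differential=node in selections.differential_regulators,
                   deregulated=node in selections.deregulated_genes,
                   chromatin_modifier=node in modifier_list)
    for row in grn_edges.itertuples(index=False):
        g.add_edge(str(row.regulator), str(row.target), kind="regulates")
    n_dropped = 0
    linked: dict[int, list[str]] = {}
    for row in pair_table.itertuples(index=False):
        if str(row.gene) in genes:
            linked.setdefault(int(row.enhancer_idx), []).append(str(row.gene))
        else:
            n_dropped += 1
    for k, targets in linked.items():
        erow = enhancers.iloc[k]
        eid = str(erow["id"])
        g.add_node(eid, kind="enhancer", enh_class=str(erow["class"]),
                   chrom=str(erow["chrom"]), start=int(erow["start"]), end=int(erow["end"]),
                   differential=False, deregulated=False, chromatin_modifier=False)
        for target in sorted(set(targets)):
            g.add_edge(eid, target, kind="enhances")
    return g, n_dropped


def extract_disease_subnetwork(
    g: nx.DiGraph,
    core_tfs: Sequence[str],
    selections: Selections,
    keep_isolated_core: bool = True,
) -> nx.DiGraph:
    """Subnetwork around core transcription factors.

    Retains the core TFs, their targets that are deregulated genes or
    selected chromatin modifiers, and the enhancers linked to any retained
    gene; dangling enhancers (no retained target) are removed. Core TFs
    without surviving targets stay as isolated nodes unless
    ``keep_isolated_core`` is False. Monotone in core_tfs.
    """
    import warnings

    core = []
    for tf in core_tfs:
        if tf in g and g.nodes[tf]["kind"] == "regulator":
            core.append(tf)
        else:
            warnings.warn(f"core TF {tf!r} not a regulator node; skipped")
    keep: set[str] = set(core)
    for tf in core:
        for _, target, data in g.out_edges(tf, data=True):
            if data.get("kind") != "regulates":
                continue
            node = g.nodes[target]
            if target in selections.deregulated_genes or (
                    node.get("chromatin_modifier") and target in selections.modifiers):
                keep.add(target)
    keep |= {m for m in selections.modifiers if m in g}
    for node, data in g.nodes(data=True):
        if data.get("kind") == "enhancer":
            if any(t in keep for _, t in g.out_edges(node)):
                keep.add(node)
    sub = g.subgraph(keep).copy()
    if not keep_isolated_core:
        sub.remove_nodes_from([n for n in core if sub.degree(n) == 0])
    # drop enhancers whose retained-gene edges were severed by the induced subgraph
    sub.remove_nodes_from([n for n, d in list(sub.nodes(data=True))
                           if d.get("kind") == "enhancer" and sub.out_degree(n) == 0])
    return sub


def write_graph(g: nx.DiGraph, prefix: str) -> None:
    """Serialize as GraphML plus flat node/edge TSVs."""
    nx.write_graphml(g, f"{prefix}.graphml")
    nodes = pd.DataFrame(
        [{"node": n, **d} for n, d in sorted(g.nodes(data=True))]
    )
    nodes.to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [{"source": u, "target": v, **d} for u, v, d in sorted(g.edges(data=True))]
    )
    edges.to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)


def read_graph(prefix: str) -> nx.DiGraph:
    return nx.read_graphml(f"{prefix}.graphml")
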