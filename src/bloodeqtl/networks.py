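"""Regulatory-network construction from significant associations.

A bipartite directed graph connects eQTL-SNPs to the probes (or genes)
whose expression they associate with; components, degree summaries and
master-regulator SNPs are read off the graph.  Co-expression among the
targets of one regulator is filtered with the Partial Correlation and
Information Theory (PCIT) algorithm of Reverter & Chan (2008): an edge
survives unless some third variable explains it, in the sense that the
edge correlation is dominated by the tolerance-scaled correlations
through that variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PcitResult",
    "build_association_graph",
    "component_summary",
    "find_master_regulators",
    "pcit_filter",
    "export_network",
    "read_network",
]

SNP_PREFIX = "snp::"
TARGET_PREFIX = "tgt::"


def build_association_graph(
    eqtl_table: pd.DataFrame,
    probe_annotation: pd.DataFrame | None = None,
    collapse_to_genes: bool = False,
) -> nx.DiGraph:
    """Bipartite SNP -> probe/gene graph of significant associations.

    ``eqtl_table`` needs columns lead_snp_id, probe_id,
    regulation_class and p_lead.  With ``collapse_to_genes`` (requires
    ``probe_annotation`` with a gene_symbol column), probes annotated to
    one gene merge into a single node; multiple probes of a gene hitting
    the same SNP accumulate as the edge's ``weight`` (multi-edge node
    pairs).  Node attribute ``kind`` is "snp" or "target".
    """
    if eqtl_table.empty:
        raise ValueError("cannot build a network from an empty table")
    g = nx.DiGraph()
    for _, row in eqtl_table.iterrows():
        snp = SNP_PREFIX + str(row["lead_snp_id"])
        target_id = str(row["probe_id"])
        if collapse_to_genes:
            if probe_annotation is None:
                raise ValueError("collapse_to_genes requires probe_annotation")
            gene = probe_annotation["gene_symbol"].get(row["probe_id"])
            if pd.notna(gene):
                target_id = str(gene)
        target = TARGET_PREFIX + target_id
        g.add_node(snp, kind="snp", label=str(row["lead_snp_id"]))
        g.add_node(target, kind="target", label=target_id)
        if g.has_edge(snp, target):
            g[snp][target]["weight"] += 1
        else:
            g.add_edge(
                snp, target, weight=1,
                regulation=row.get("regulation_class", "unknown"),
                p_value=float(row["p_lead"]),
            )
    return g


def component_summary(network: nx.DiGraph, min_size: int = 3) -> dict:
    """Connected components of the undirected skeleton plus degree stats.

    Returns component node sets, the size histogram restricted to
    components with at least ``min_size`` nodes, and the mean undirected
    neighbor count over all nodes.
    """
    comps = [set(c) for c in nx.connected_components(network.to_undirected())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    big = [c for c in comps if len(c) >= min_size]
    hist: dict[int, int] = {}
    for c in big:
        hist[len(c)] = hist.get(len(c), 0) + 1
    n_nodes = network.number_of_nodes()
    mean_degree = (
        2 * network.number_of_edges() / n_nodes if n_nodes else float("nan")
    )
    return {
        "components": comps,
        "size_histogram": dict(sorted(hist.items())),
        "n_components_min_size": len(big),
        "mean_degree": mean_degree,
    }


def find_master_regulators(network: nx.DiGraph, min_targets: int = 10) -> pd.DataFrame:
    """SNP nodes regulating at least ``min_targets`` distinct targets.

    Sorted by out-degree descending, then SNP id for determinism.
    """
    rows = []
    for node, data in network.nodes(data=True):
        if data.get("kind") != "snp":
            continue
        degree = network.out_degree(node)
        if degree >= min_targets:
            n_distant = sum(
                1 for _, _, d in network.out_edges(node, data=True)
                if d.get("regulation") == "distant"
            )
            rows.append(
                {"snp_id": data.get("label", node), "n_targets": degree,
                 "n_distant": n_distant}
            )
    rows.sort(key=lambda r: (-r["n_targets"], r["snp_id"]))
    return pd.DataFrame(rows, columns=["snp_id", "n_targets", "n_distant"])


@dataclass
class PcitResult:
    """PCIT outcome: correlations, kept-edge mask, trio diagnostics."""

    correlations: pd.DataFrame
    kept: pd.DataFrame  # boolean, symmetric, False on the diagonal
    n_trios_tested: int
    n_trios_skipped: int

    def significant_edges(self) -> pd.DataFrame:
        names = self.correlations.index
        rows = []
        mask = self.kept.to_numpy()
        r = self.correlations.to_numpy()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if mask[i, j]:
                    rows.append(
                        {"var_a": names[i], "var_b": names[j], "r": r[i, j]}
                    )
        return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])


def pcit_filter(data: pd.DataFrame) -> PcitResult:
    """PCIT co-expression filtering of a variables-in-columns matrix.

    For every unordered trio (x, y, z) the three first-order partial
    correlations are formed,

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

    and the trio tolerance is the mean of the three partial-to-marginal
    ratios.  The edge (x, y) is discarded when, for some z, |r_xy| <=
    |eps * r_xz| and |r_xy| <= |eps * r_yz|.  Trios with a unit
    correlation in a denominator are skipped as degenerate.  With two
    variables the single edge is kept vacuously.
    """
    if data.shape[0] < 4:
        raise ValueError("PCIT needs at least 4 observations")
    if data.shape[1] < 2:
        raise ValueError("PCIT needs at least 2 variables")
    names = data.columns
    r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    m = len(names)
    kept = ~np.eye(m, dtype=bool)
    n_tested = 0
    n_skipped = 0
    # partial[c, a, b] = r_ab.c (first-order partial of a,b given c)
    with np.errstate(divide="ignore", invalid="ignore"):
        partial = np.empty((m, m, m))
        for c in range(m):
            rc = r[:, c]
            denom = np.sqrt((1 - rc[:, None] ** 2) * (1 - rc[None, :] ** 2))
            partial[c] = (r - rc[:, None] * rc[None, :]) / denom
    for z in range(m):
        for x in range(m):
            if x == z:
                continue
            for y in range(x + 1, m):
                if y == z:
                    continue
                n_tested += 1
                if 1.0 in (abs(r[x, z]), abs(r[y, z]), abs(r[x, y])):
                    n_skipped += 1
                    continue
                with np.errstate(divide="ignore", invalid="ignore"):
                    eps = (
                        partial[z, x, y] / r[x, y]
                        + partial[y, x, z] / r[x, z]
                        + partial[x, y, z] / r[y, z]
                    ) / 3.0
                if not np.isfinite(eps):
                    n_skipped += 1
                    continue
                if abs(r[x, y]) <= abs(eps * r[x, z]) and abs(r[x, y]) <= abs(
                    eps * r[y, z]
                ):
                    kept[x, y] = kept[y, x] = False
    return PcitResult(
        correlations=pd.DataFrame(r, index=names, columns=names),
        kept=pd.DataFrame(kept, index=names, columns=names),
        n_trios_tested=n_tested,
        n_trios_skipped=n_skipped,
    )


def export_network(network: nx.DiGraph, path, fmt: str = "sif") -> None:
    """Write the association graph as SIF or an edge-list TSV.

    SIF lines are ``snp <tab> relation <tab> target`` with the
    local/distant label as the relation; the TSV adds weight and
    p-value columns.  Edges are written in sorted order so identical
    graphs produce identical bytes.
    """
    edges = sorted(network.edges(data=True))
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in edges:
                fh.write(
                    f"{network.nodes[u]['label']}\t{d.get('regulation', 'unknown')}\t"
                    f"{network.nodes[v]['label']}\n"
                )
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("snp_id\ttarget_id\tregulation\tweight\tp_value\n")
            for u, v, d in edges:
                fh.write(
                    f"{network.nodes[u]['label']}\t{network.nodes[v]['label']}\t"
                    f"{d.get('regulation', 'unknown')}\t{d.get('weight', 1)}\t"
                    f"{d.get('p_value', float('nan')):.6g}\n"
                )
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: sif, tsv")


def read_network(path, fmt: str = "sif") -> nx.DiGraph:
    """Read a graph written by :func:`export_network` (lossless for SIF
    topology/relations; the TSV reader also restores weights and p)."""
    g = nx.DiGraph()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if fmt == "sif":
        for line in lines:
            if not line.strip():
                continue
            snp, relation, target = line.split("\t")
            g.add_node(SNP_PREFIX + snp, kind="snp", label=snp)
            g.add_node(TARGET_PREFIX + target, kind="target", label=target)
            g.add_edge(SNP_PREFIX + snp, TARGET_PREFIX + target, regulation=relation)
    elif fmt == "tsv":
        for line in lines[1:]:
            if not line.strip():
                continue
            snp, target, relation, weight, p = line.split("\t")
            g.add_node(SNP_PREFIX + snp, kind="snp", label=snp)
            g.add_node(TARGET_PREFIX + target, kind="target", label=target)
            g.add_edge(
                SNP_PREFIX + snp, TARGET_PREFIX + target, regulation=relation,
                weight=int(weight), p_value=float(p),
            )
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: sif, tsv")
    return g
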