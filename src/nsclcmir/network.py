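"""Bipartite miRNA -> target regulatory network integration.

An edge (m, g) survives integration iff it is predicted by at least
``min_programs`` programs, the miRNA is differentially *up* in some subtype
S, and the gene is differentially *down* in that same S (repression
consistency): a miRNA over-expressed in a subtype can only explain the
down-regulation of its targets in that subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import TargetTable

__all__ = ["RegulatoryNetwork", "integrate", "multi_mirna_targets",
           "export_network", "read_network", "gene_directions_from_targets"]


@dataclass
class RegulatoryNetwork:
    """Directed bipartite graph: miRNA nodes -> gene nodes.

    Node attributes: ``kind`` ('mirna'|'gene') and ``subtype`` (the miRNA's
    up-subtype / the gene's down-subtype).  Edge attributes: ``programs``
    (frozenset) and ``subtype``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def mirnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["kind"] == "mirna")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["kind"] == "gene")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges())

    def mirnas_up_in(self, subtype: str) -> list[str]:
        return sorted(m for m in self.mirnas
                      if self.graph.nodes[m]["subtype"] == subtype)

    def targets_of(self, mirnas) -> list[str]:
        if isinstance(mirnas, str):
            mirnas = [mirnas]
        out = set()
        for m in mirnas:
            if m in self.graph:
                out.update(self.graph.successors(m))
        return sorted(out)


def _as_direction_map(items) -> dict[str, str]:
    if isinstance(items, dict):
        return dict(items)
    if isinstance(items, pd.DataFrame):
        return dict(zip(items.iloc[:, 0], items.iloc[:, 1]))
    return {feature: subtype for feature, subtype in items}


def integrate(de_mirnas, de_genes, targets: TargetTable,
              min_programs: int = 1) -> RegulatoryNetwork:
    """Build the repression-consistent network.

    ``de_mirnas`` maps miRNA -> subtype of over-expression; ``de_genes``
    maps gene -> subtype of *down*-regulation (both accept dicts, (feature,
    subtype) iterables, or two-column DataFrames).  Nodes without surviving
    edges are dropped; a target table that touches no DE feature yields an
    empty network with a warning.
    """
    mirna_up = _as_direction_map(de_mirnas)
    gene_down = _as_direction_map(de_genes)
    g = nx.DiGraph()
    for _, row in targets.data.iterrows():
        m, gene, progs = row["mirna"], row["gene"], row["programs"]
        if len(progs) < min_programs:
            continue
        if m not in mirna_up or gene not in gene_down:
            continue
        if mirna_up[m] != gene_down[gene]:
            continue
        g.add_node(m, kind="mirna", subtype=mirna_up[m])
        g.add_node(gene, kind="gene", subtype=gene_down[gene])
        g.add_edge(m, gene, programs=frozenset(progs), subtype=mirna_up[m])
    if g.number_of_edges() == 0:
        warnings.warn("integration produced an empty network "
                      "(no predicted pair links DE features with "
                      "opposite directions)", stacklevel=2)
    return RegulatoryNetwork(graph=g)


def multi_mirna_targets(net: RegulatoryNetwork) -> list[str]:
    """Genes regulated by >= 2 miRNAs, by in-degree descending
    (alphabetical within ties)."""
    degs = [(gene, net.graph.in_degree(gene)) for gene in net.genes]
    multi = [(g, d) for g, d in degs if d >= 2]
    multi.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in multi]


def export_network(net: RegulatoryNetwork, path, graphml_path=None) -> None:
    """Write the edge list as TSV (and optionally GraphML for viewers).

    Rows are sorted by (mirna, gene) so exports are byte-stable.
    """
    rows = []
    for m, gene in net.edges():
        data = net.graph.edges[m, gene]
        rows.append({
            "mirna": m,
            "gene": gene,
            "programs": ";".join(sorted(data["programs"])),
            "mirna_up_in": data["subtype"],
            "gene_down_in": data["subtype"],
        })
    pd.DataFrame(rows, columns=["mirna", "gene", "programs",
                                "mirna_up_in", "gene_down_in"]
                 ).to_csv(path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.DiGraph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, kind=d["kind"], subtype=d["subtype"])
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, programs=";".join(sorted(d["programs"])),
                       subtype=d["subtype"])
        nx.write_graphml(g, graphml_path)


def read_network(path) -> RegulatoryNetwork:
    """Read an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.DiGraph()
    for _, row in df.iterrows():
        progs = frozenset(row["programs"].split(";"))
        g.add_node(row["mirna"], kind="mirna", subtype=row["mirna_up_in"])
        g.add_node(row["gene"], kind="gene", subtype=row["gene_down_in"])
        g.add_edge(row["mirna"], row["gene"], programs=progs,
                   subtype=row["mirna_up_in"])
    return RegulatoryNetwork(graph=g)


def gene_directions_from_targets(targets: TargetTable) -> dict[str, str]:
    """Down-subtype implied for each target gene by its miRNAs' annotations
    (a gene targeted only by SCC-up miRNAs is down in SCC).  Raises if two
    annotated miRNAs imply conflicting directions for one gene."""
    out: dict[str, str] = {}
    for _, row in targets.data.iterrows():
        if pd.isna(row["direction"]):
            continue
        prev = out.setdefault(row["gene"], row["direction"])
        if prev != row["direction"]:
            raise ValueError(
                f"gene {row['gene']!r} implied down in both subtypes")
    return out
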