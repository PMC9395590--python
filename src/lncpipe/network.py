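"""Bipartite lncRNA-mRNA regulatory networks: build, export, re-import.

Edges are TargetPairs restricted to differentially expressed lncRNAs (and
optionally DE genes); node kind ("lncRNA"/"mRNA") and edge attributes (mode,
cis category/distance or r/sign) ride along into every export format. An
optional user-supplied interaction table can be merged in place of live
protein-interaction database queries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import networkx as nx

from .errors import ValidationError

__all__ = ["RegulatoryNetwork", "build_network", "export_network", "import_network"]


def _edge_key(mode: str, category: str | None) -> str:
    return f"{mode}_{category}" if category else mode


@dataclass
class RegulatoryNetwork:
    """A bipartite multigraph: lncRNA nodes on one side, mRNA on the other."""

    graph: nx.MultiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Canonical (lnc, gene, interaction-token) triples."""
        out = set()
        for u, v, k in self.graph.edges(keys=True):
            lnc, gene = (u, v) if self.graph.nodes[u]["kind"] == "lncRNA" else (v, u)
            out.add((lnc, gene, k))
        return out

    def degree_table(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def is_bipartite(self) -> bool:
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] == self.graph.nodes[v]["kind"]:
                return False
        return True


def build_network(
    pairs,
    de_lnc: set[str],
    de_genes: set[str] | None = None,
    require_de_gene: bool = False,
    proximity_bp: int | None = 10000,
    extra_interactions=None,
) -> RegulatoryNetwork:
    """Build the regulatory network from target pairs and DE calls.

    Edges keep pairs whose lncRNA is differentially expressed; with
    ``require_de_gene`` the gene must be DE too. cis pairs farther than
    ``proximity_bp`` are dropped. ``extra_interactions`` is an optional
    iterable of (node_a, node_b, token) rows (e.g. a user-supplied
    protein-interaction table) merged as additional mRNA-mRNA edges.
    """
    g = nx.MultiGraph()
    for p in pairs:
        if p.lnc_id not in de_lnc:
            continue
        if require_de_gene and (de_genes is None or p.gene_id not in de_genes):
            continue
        if p.mode == "cis" and proximity_bp is not None and p.distance_bp > proximity_bp:
            continue
        key = _edge_key(p.mode, p.cis_category if p.mode == "cis" else p.sign)
        g.add_node(p.lnc_id, kind="lncRNA")
        g.add_node(p.gene_id, kind="mRNA")
        if not g.has_edge(p.lnc_id, p.gene_id, key=key):
            attrs = {"mode": p.mode}
            if p.mode == "cis":
                attrs.update(category=p.cis_category, distance_bp=p.distance_bp)
            else:
                attrs.update(r=p.r, sign=p.sign)
            g.add_edge(p.lnc_id, p.gene_id, key=key, **attrs)
    if extra_interactions:
        for a, b, token in extra_interactions:
            g.add_node(a, kind=g.nodes[a]["kind"] if a in g else "mRNA")
            g.add_node(b, kind=g.nodes[b]["kind"] if b in g else "mRNA")
            g.add_edge(a, b, key=str(token), mode="external")
    return RegulatoryNetwork(g)


def export_network(net: RegulatoryNetwork, fmt: str, path) -> None:
    """Write the network as SIF, GraphML or an edge-attribute TSV.

    SIF lines read ``lnc_id <interaction> gene_id`` with tokens such as
    ``cis_upstream`` or ``trans_positive``; node/edge attribute tables are
    written alongside (``<path>.nodes.tsv``).
    """
    fmt = fmt.lower()
    path = str(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, k in sorted(net.graph.edges(keys=True)):
                lnc, gene = (u, v) if net.graph.nodes[u]["kind"] == "lncRNA" else (v, u)
                fh.write(f"{lnc}\t{k}\t{gene}\n")
        _write_node_table(net, path + ".nodes.tsv")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt in ("tsv", "edge-tsv"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "interaction", "target", "mode",
                        "category", "distance_bp", "r", "sign"])
            for u, v, k, d in sorted(net.graph.edges(keys=True, data=True)):
                lnc, gene = (u, v) if net.graph.nodes[u]["kind"] == "lncRNA" else (v, u)
                w.writerow([
                    lnc, k, gene, d.get("mode", ""),
                    d.get("category", ""), d.get("distance_bp", ""),
                    d.get("r", ""), d.get("sign", ""),
                ])
        _write_node_table(net, path + ".nodes.tsv")
    else:
        raise ValidationError(f"unknown network export format {fmt!r}")


def _write_node_table(net: RegulatoryNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("node\tkind\n")
        for n, d in sorted(net.graph.nodes(data=True)):
            fh.write(f"{n}\t{d.get('kind', '')}\n")


def import_network(fmt: str, path) -> RegulatoryNetwork:
    """Re-read a network written by :func:`export_network`."""
    fmt = fmt.lower()
    path = str(path)
    g = nx.MultiGraph()
    if fmt == "graphml":
        raw = nx.read_graphml(path, force_multigraph=True)
        for n, d in raw.nodes(data=True):
            g.add_node(n, **d)
        for u, v, k, d in raw.edges(keys=True, data=True):
            g.add_edge(u, v, key=k, **d)
        return RegulatoryNetwork(g)

    nodes_path = path + ".nodes.tsv"
    kinds: dict[str, str] = {}
    with open(nodes_path) as fh:
        next(fh)
        for line in fh:
            n, kind = line.rstrip("\n").split("\t")
            kinds[n] = kind
    if fmt == "sif":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                lnc, token, gene = line.rstrip("\n").split("\t")
                g.add_node(lnc, kind=kinds.get(lnc, "lncRNA"))
                g.add_node(gene, kind=kinds.get(gene, "mRNA"))
                g.add_edge(lnc, gene, key=token)
        return RegulatoryNetwork(g)
    if fmt in ("tsv", "edge-tsv"):
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                lnc, gene, token = row["source"], row["target"], row["interaction"]
                g.add_node(lnc, kind=kinds.get(lnc, "lncRNA"))
                g.add_node(gene, kind=kinds.get(gene, "mRNA"))
                attrs = {"mode": row["mode"]}
                if row["category"]:
                    attrs["category"] = row["category"]
                if row["distance_bp"]:
                    attrs["distance_bp"] = int(row["distance_bp"])
                if row["r"]:
                    attrs["r"] = float(row["r"])
                if row["sign"]:
                    attrs["sign"] = row["sign"]
                g.add_edge(lnc, gene, key=token, **attrs)
        return RegulatoryNetwork(g)
    raise ValidationError(f"unknown network import format {fmt!r}")
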