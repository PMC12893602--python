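"""Tripartite miRNA-TF-mRNA regulatory network and FFL motif ranking.

The network is a typed directed graph over (role, id) nodes with three
edge types: TF->mRNA activation and miRNA->TF / miRNA->mRNA repression.
A feed-forward loop (FFL) is a triple (tf, gene, mirna) such that all of
tf->gene, mirna-|tf and mirna-|gene are present. Motifs are ranked by the
sum of their members' degree centralities; the top-ranked triple is the
predominant motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_TF = "TF"
ROLE_MRNA = "mRNA"
ROLE_MIRNA = "miRNA"

EDGE_TF_MRNA = "tf_mrna"
EDGE_MIRNA_TF = "mirna_tf"
EDGE_MIRNA_MRNA = "mirna_mrna"


@dataclass
class RegulatoryNetwork:
    """Typed tripartite graph; nodes are (role, id) pairs."""

    graph: nx.DiGraph

    def nodes_with_role(self, role: str) -> list[tuple[str, str]]:
        return sorted(n for n in self.graph.nodes if n[0] == role)

    def edges_with_type(self, edge_type: str):
        return [
            (u, v) for u, v, t in self.graph.edges(data="edge_type") if t == edge_type
        ]


@dataclass(frozen=True)
class FFLMotif:
    """One (TF, mRNA, miRNA) feed-forward-loop instance."""

    tf: str
    gene: str
    mirna: str
    member_degrees: tuple[float, float, float] | None = None
    motif_score: float | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.tf, self.gene, self.mirna)


def assemble_network(
    tf_gene: pd.DataFrame, mir_gene: pd.DataFrame, mir_tf: pd.DataFrame
) -> RegulatoryNetwork:
    """Combine the three calibrated pair tables into one typed graph.

    Node identity is the (role, id) pair, so an identifier appearing both
    as a TF and as an mRNA becomes two distinct nodes (logged); duplicate
    rows collapse to a single edge.
    """
    g = nx.DiGraph()
    g.add_edges_from(
        ((ROLE_TF, t), (ROLE_MRNA, ge), {"edge_type": EDGE_TF_MRNA})
        for t, ge in zip(tf_gene["tf"], tf_gene["gene"])
    )
    g.add_edges_from(
        ((ROLE_MIRNA, m), (ROLE_TF, t), {"edge_type": EDGE_MIRNA_TF})
        for m, t in zip(mir_tf["mirna"], mir_tf["target"])
    )
    g.add_edges_from(
        ((ROLE_MIRNA, m), (ROLE_MRNA, ge), {"edge_type": EDGE_MIRNA_MRNA})
        for m, ge in zip(mir_gene["mirna"], mir_gene["target"])
    )
    ids_by_role: dict[str, set] = {}
    for role, name in g.nodes:
        ids_by_role.setdefault(role, set()).add(name)
    roles = list(ids_by_role)
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1:]:
            shared = ids_by_role[r1] & ids_by_role[r2]
            if shared:
                logger.info(
                    "assemble_network: %d ids appear as both %s and %s; kept as distinct nodes",
                    len(shared), r1, r2,
                )
    return RegulatoryNetwork(g)


def network_summary(network: RegulatoryNetwork) -> dict:
    """Node counts per role, edge counts per type, and their totals."""
    g = network.graph
    roles = {ROLE_TF: 0, ROLE_MRNA: 0, ROLE_MIRNA: 0}
    for role, _ in g.nodes:
        roles[role] += 1
    types = {EDGE_TF_MRNA: 0, EDGE_MIRNA_TF: 0, EDGE_MIRNA_MRNA: 0}
    for _, _, t in g.edges(data="edge_type"):
        types[t] += 1
    return {
        "n_tf": roles[ROLE_TF],
        "n_mrna": roles[ROLE_MRNA],
        "n_mirna": roles[ROLE_MIRNA],
        "n_nodes": g.number_of_nodes(),
        "n_tf_mrna_edges": types[EDGE_TF_MRNA],
        "n_mirna_tf_edges": types[EDGE_MIRNA_TF],
        "n_mirna_mrna_edges": types[EDGE_MIRNA_MRNA],
        "n_edges": g.number_of_edges(),
    }


def degree_centrality(network: RegulatoryNetwork, normalized: bool = False) -> dict:
    """Total degree (in + out over all edge types) per (role, id) node.

    With ``normalized=True`` degrees are divided by (total nodes - 1), as
    in the standard normalized degree centrality.
    """
    g = network.graph
    denom = (g.number_of_nodes() - 1) if normalized else 1
    if denom <= 0:
        denom = 1
    return {n: d / denom for n, d in g.degree()}


def enumerate_ffls(network: RegulatoryNetwork) -> list[FFLMotif]:
    """All (tf, gene, mirna) triples whose three defining edges exist.

    Deterministic order: sorted by (tf, gene, mirna) identifiers.
    """
    g = network.graph
    motifs = []
    for node in g.nodes:
        if node[0] != ROLE_MIRNA:
            continue
        succ = list(g.successors(node))
        tf_targets = [v for v in succ if v[0] == ROLE_TF]
        gene_targets = {v[1] for v in succ if v[0] == ROLE_MRNA}
        if not gene_targets:
            continue
        for tf_node in tf_targets:
            for gene_node in g.successors(tf_node):
                if gene_node[0] == ROLE_MRNA and gene_node[1] in gene_targets:
                    motifs.append(FFLMotif(tf=tf_node[1], gene=gene_node[1], mirna=node[1]))
    motifs.sort(key=lambda m: m.key)
    return motifs


def rank_motifs(
    ffls: list[FFLMotif], centrality: dict, rule: str = "sum"
) -> list[FFLMotif]:
    """Score each motif from its members' centralities and rank descending.

    ``sum`` (default) scores a motif by the sum of the three member
    centralities; ``max`` by the maximum. Ties break lexicographically on
    (tf, gene, mirna); the first element is the predominant motif.
    """
    if rule not in {"sum", "max"}:
        raise ValueError(f"unknown ranking rule {rule!r}")
    if not ffls:
        logger.warning("rank_motifs: empty motif list")
        return []
    scored = []
    for m in ffls:
        degs = (
            centrality[(ROLE_TF, m.tf)],
            centrality[(ROLE_MRNA, m.gene)],
            centrality[(ROLE_MIRNA, m.mirna)],
        )
        score = sum(degs) if rule == "sum" else max(degs)
        scored.append(replace(m, member_degrees=degs, motif_score=float(score)))
    scored.sort(key=lambda m: (-m.motif_score, m.key))
    return scored


def motif_table(ranked: list[FFLMotif]) -> pd.DataFrame:
    """Ranked motifs as a flat table (rank, members, degrees, score)."""
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "tf": [m.tf for m in ranked],
            "gene": [m.gene for m in ranked],
            "mirna": [m.mirna for m in ranked],
            "tf_degree": [m.member_degrees[0] if m.member_degrees else None for m in ranked],
            "gene_degree": [m.member_degrees[1] if m.member_degrees else None for m in ranked],
            "mirna_degree": [m.member_degrees[2] if m.member_degrees else None for m in ranked],
            "motif_score": [m.motif_score for m in ranked],
        }
    )


def write_edge_list(network: RegulatoryNetwork, path) -> None:
    """Edge-list TSV (source, target, edge_type) loadable by graph viewers."""
    rows = [
        {"source": u[1], "target": v[1], "edge_type": t}
        for u, v, t in network.graph.edges(data="edge_type")
    ]
    pd.DataFrame(rows, columns=["source", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )
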