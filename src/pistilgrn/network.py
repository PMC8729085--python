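"""Regulatory-network assembly, topology, hubs, sex-specific TFs, subnetworks.

A directed TF -> target edge enters a stage network only when the pair
passed the co-expression thresholds, the TF's binding motif is enriched in
its co-expressed partner set (Bonferroni-adjusted p below the cutoff), and
the target's promoter carries a predicted site for that motif. Hubs are the
top decile of nodes by (undirected) degree; sex-specific expression uses
the FPKM >= 1 expression rule per (sex, stage); the subnetwork around seed
TFs is the union of first-order neighborhoods across stage networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import GroupProfile

__all__ = [
    "TopologyStats",
    "HubSet",
    "SexSpecificCall",
    "assemble_network",
    "topology",
    "select_hubs",
    "sex_specific_calls",
    "extract_subnetwork",
    "export_network",
]


@dataclass
class TopologyStats:
    total_nodes: int
    total_edges: int
    average_degree: float
    average_clustering: float
    average_path_length: float
    average_connectivity: float

    def as_dict(self) -> dict:
        return {
            "total_nodes": self.total_nodes,
            "total_edges": self.total_edges,
            "average_degree": self.average_degree,
            "average_clustering": self.average_clustering,
            "average_path_length": self.average_path_length,
            "average_connectivity": self.average_connectivity,
        }


@dataclass
class HubSet:
    genes: list[str]
    degrees: dict[str, int]
    fraction: float = 0.10


@dataclass
class SexSpecificCall:
    gene_id: str
    expressed: dict[str, bool]  # "sex:stage" -> expressed flag
    verdict: str  # female-specific | male-specific | shared | silent
    stages: list[str] = field(default_factory=list)


def assemble_network(
    called_edges: pd.DataFrame,
    tf_annotation: pd.DataFrame,
    enrichment: pd.DataFrame,
    hits: pd.DataFrame,
    motif_adj_p: float = 0.001,
    sex: str = "",
    stage: str = "",
    gene_subset=None,
) -> nx.DiGraph:
    """Directed TF -> target network from co-expression plus motif evidence.

    ``called_edges`` is the thresholded output of the co-expression stage;
    ``enrichment`` the per-motif Fisher results; ``hits`` the boolean
    gene x motif promoter-scan matrix. ``gene_subset`` restricts the network
    to one stage's DEG set.
    """
    tf_motif: dict[str, str] = {}
    for _, row in tf_annotation.iterrows():
        if not row["motif_id"]:
            warnings.warn(f"TF {row['gene_id']} has no assigned motif; excluded")
            continue
        tf_motif[row["gene_id"]] = row["motif_id"]
    enriched = {
        row["motif_id"]: row["adj_p"]
        for _, row in enrichment.iterrows()
        if row["adj_p"] < motif_adj_p
    }
    subset = set(gene_subset) if gene_subset is not None else None
    g = nx.DiGraph(sex=sex, stage=stage)
    families = dict(zip(tf_annotation["gene_id"], tf_annotation["family"]))
    for _, e in called_edges.iterrows():
        a, b = e["gene_a"], e["gene_b"]
        if a == b:
            continue
        if subset is not None and (a not in subset or b not in subset):
            continue
        for tf, target in ((a, b), (b, a)):
            motif = tf_motif.get(tf)
            if motif is None or motif not in enriched:
                continue
            if target not in hits.index or not bool(hits.at[target, motif]):
                continue
            g.add_node(tf, is_tf=True, family=families.get(tf, ""))
            g.add_node(target, is_tf=target in tf_motif, family=families.get(target, ""))
            g.add_edge(
                tf,
                target,
                pcc=float(e["pcc"]),
                mr_score=float(e["mr_score"]),
                motif_id=motif,
                motif_adj_p=float(enriched[motif]),
            )
    return g


def topology(network: nx.Graph) -> TopologyStats:
    """Topology statistics on the undirected projection.

    Path length averages shortest paths over reachable pairs only;
    connectivity is the mean over nodes of the mean degree of their
    neighbors (isolated nodes contribute 0).
    """
    u = network.to_undirected() if network.is_directed() else network
    n = u.number_of_nodes()
    if n == 0:
        return TopologyStats(0, 0, 0.0, 0.0, 0.0, 0.0)
    m = u.number_of_edges()
    avg_degree = 2.0 * m / n
    clustering = nx.average_clustering(u) if n else 0.0
    total_len, total_pairs = 0, 0
    for comp in nx.connected_components(u):
        sub = u.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, dists in nx.shortest_path_length(sub):
            total_len += sum(dists.values())
            total_pairs += len(dists) - 1  # exclude the node itself
    path_length = total_len / total_pairs if total_pairs else 0.0
    neigh = nx.average_neighbor_degree(u)
    connectivity = float(np.mean(list(neigh.values()))) if neigh else 0.0
    return TopologyStats(
        total_nodes=n,
        total_edges=m,
        average_degree=avg_degree,
        average_clustering=clustering,
        average_path_length=path_length,
        average_connectivity=connectivity,
    )


def select_hubs(network: nx.Graph, fraction: float = 0.10) -> HubSet:
    """Top ``ceil(fraction * N)`` nodes by degree, ties broken by gene id."""
    u = network.to_undirected() if network.is_directed() else network
    degrees = dict(u.degree())
    if not degrees:
        return HubSet(genes=[], degrees={}, fraction=fraction)
    k = math.ceil(fraction * len(degrees))
    ordered = sorted(degrees, key=lambda g: (-degrees[g], g))
    hubs = ordered[:k]
    return HubSet(genes=hubs, degrees={g: degrees[g] for g in hubs}, fraction=fraction)


def sex_specific_calls(
    profile: GroupProfile,
    genes,
    stages,
    expressed_threshold: float = 1.0,
) -> list[SexSpecificCall]:
    """Expression-based sex specificity per gene over the given stages.

    Expressed means FPKM >= 1 (the boundary counts as expressed). A gene is
    female-specific at a stage when it is expressed in F and not in M there;
    the verdict lists the qualifying stages. Genes specific in both
    directions at different stages are reported as shared.
    """
    calls = []
    for gene in genes:
        flags = {}
        for stage in stages:
            for sex in ("F", "M"):
                key = f"{sex}:{stage}"
                if key not in profile.values.columns:
                    raise ValueError(f"group {key} missing from the profile")
                flags[key] = bool(profile.values.at[gene, key] >= expressed_threshold)
        f_stages = [s for s in stages if flags[f"F:{s}"] and not flags[f"M:{s}"]]
        m_stages = [s for s in stages if flags[f"M:{s}"] and not flags[f"F:{s}"]]
        if not any(flags.values()):
            verdict, spec = "silent", []
        elif f_stages and not m_stages:
            verdict, spec = "female-specific", f_stages
        elif m_stages and not f_stages:
            verdict, spec = "male-specific", m_stages
        else:
            verdict, spec = "shared", []
        calls.append(
            SexSpecificCall(gene_id=gene, expressed=flags, verdict=verdict, stages=spec)
        )
    return calls


def extract_subnetwork(networks: list[nx.DiGraph], seed_genes) -> nx.MultiDiGraph:
    """Union of first-order neighborhoods of the seeds across stage networks.

    Edges keep a ``stage``/``sex`` tag from their source network; the same
    regulatory pair found in two stage networks yields two tagged edges.
    """
    seeds = set(seed_genes)
    sub = nx.MultiDiGraph()
    found = False
    for net in networks:
        present = seeds & set(net.nodes)
        if not present:
            continue
        found = True
        selected = set(present)
        for s in present:
            selected |= set(net.successors(s)) | set(net.predecessors(s))
        for node in selected:
            attrs = dict(net.nodes[node])
            attrs["is_seed"] = node in seeds
            sub.add_node(node, **attrs)
        for a, b, data in net.edges(data=True):
            if a in selected and b in selected:
                sub.add_edge(
                    a, b, stage=net.graph.get("stage", ""), sex=net.graph.get("sex", ""), **data
                )
    if not found:
        warnings.warn("no seed gene found in any network; subnetwork is empty")
    return sub


def export_network(network: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as SIF, GraphML or an edge-list TSV."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in network.edges():
                fh.write(f"{a}\tregulates\t{b}\n")
    elif fmt == "graphml":
        clean = network.copy()
        for _, data in clean.nodes(data=True):
            for k, v in list(data.items()):
                if v is None:
                    data[k] = ""
        nx.write_graphml(clean, path)
    elif fmt == "tsv":
        rows = [
            {"source": a, "target": b, **data} for a, b, data in network.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
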