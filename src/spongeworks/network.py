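"""Assembly of the miRNA-centred tripartite ceRNA (sponge) network.

A sponge triplet is one miRNA with at least one MRE on a differentially
expressed lncRNA and at least one MRE on a differentially expressed mRNA
(the "common miRNA" rule).  The co-regulation filter keeps triplets in
which lncRNA and mRNA move in the same direction, opposite to the miRNA —
the direction pattern the sponge hypothesis predicts: a lost miRNA
de-represses both of its targets, an over-expressed one represses both.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import DEResult, MRESite, SpongeTriplet
from . import io as io_formats

__all__ = [
    "CeRNANetwork",
    "build_global_network",
    "filter_coregulated",
    "network_stats",
    "export_network",
]


@dataclass
class CeRNANetwork:
    """Tripartite node/edge sets plus the triplet list they support."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    triplets: list[SpongeTriplet] = field(default_factory=list)

    def validate(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("role") not in ("miRNA", "lncRNA", "mRNA"):
                raise ValueError(f"node {node!r} has invalid role")
        for u, v, data in self.graph.edges(data=True):
            if data.get("n_sites", 0) < 1:
                raise ValueError(f"edge ({u},{v}) lacks MRE support")
        for t in self.triplets:
            if not self.graph.has_edge(t.mirna_id, t.lncrna_id):
                raise ValueError(f"triplet {t.key}: missing miRNA-lncRNA edge")
            if not self.graph.has_edge(t.mirna_id, t.mrna_id):
                raise ValueError(f"triplet {t.key}: missing miRNA-mRNA edge")


def _direction_map(de_results: Sequence[DEResult] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(de_results, Mapping):
        return dict(de_results)
    return {r.feature_id: r.direction for r in de_results}


def build_global_network(
    sites: Sequence[MRESite],
    de_results: Sequence[DEResult] | Mapping[str, str],
    lncrna_ids: Iterable[str],
    mrna_ids: Iterable[str],
) -> CeRNANetwork:
    """Global miRNA–ceRNA interaction network over DE features only.

    Nodes are differentially expressed miRNAs, lncRNAs and mRNAs; an edge
    miRNA→ceRNA requires at least one MRE; a triplet is emitted for every
    miRNA with edges to both a lncRNA and an mRNA (common-miRNA rule).
    Every feature carrying a site must appear in the DE results.
    """
    directions = _direction_map(de_results)
    lnc_set = set(lncrna_ids)
    mrna_set = set(mrna_ids)

    site_counts: dict[tuple[str, str], int] = {}
    for s in sites:
        if s.mirna_id not in directions:
            raise ValueError(f"miRNA {s.mirna_id!r} absent from DE results")
        if s.target_id not in directions:
            raise ValueError(f"target {s.target_id!r} absent from DE results")
        key = (s.mirna_id, s.target_id)
        site_counts[key] = site_counts.get(key, 0) + 1

    net = CeRNANetwork()
    g = net.graph
    lnc_edges: dict[str, list[str]] = {}
    mrna_edges: dict[str, list[str]] = {}
    for (mid, tid), n_sites in sorted(site_counts.items()):
        if directions.get(mid, "ns") == "ns" or directions.get(tid, "ns") == "ns":
            continue
        if tid in lnc_set:
            role = "lncRNA"
            lnc_edges.setdefault(mid, []).append(tid)
        elif tid in mrna_set:
            role = "mRNA"
            mrna_edges.setdefault(mid, []).append(tid)
        else:
            continue  # target not classified as either ceRNA class
        g.add_node(mid, role="miRNA", direction=directions[mid])
        g.add_node(tid, role=role, direction=directions[tid])
        g.add_edge(mid, tid, n_sites=n_sites)

    for mid in sorted(set(lnc_edges) & set(mrna_edges)):
        for lid in lnc_edges[mid]:
            for gid in mrna_edges[mid]:
                net.triplets.append(
                    SpongeTriplet(
                        mirna_id=mid,
                        lncrna_id=lid,
                        mrna_id=gid,
                        mirna_direction=directions[mid],
                        lncrna_direction=directions[lid],
                        mrna_direction=directions[gid],
                        n_sites_lncrna=site_counts[(mid, lid)],
                        n_sites_mrna=site_counts[(mid, gid)],
                    )
                )
    net.validate()
    return net


def _coregulated(t: SpongeTriplet) -> bool:
    dirs = (t.mirna_direction, t.lncrna_direction, t.mrna_direction)
    if "ns" in dirs:
        return False
    return (
        t.lncrna_direction == t.mrna_direction
        and t.lncrna_direction != t.mirna_direction
    )


def filter_coregulated(network: CeRNANetwork, permissive: bool = False) -> CeRNANetwork:
    """Keep triplets matching the sponge direction rule.

    Default: lncRNA and mRNA share a direction opposite to the miRNA's.
    ``permissive=True`` keeps any triplet whose three members are all
    differentially expressed, regardless of direction pattern.
    """
    if permissive:
        kept = [
            t
            for t in network.triplets
            if "ns"
            not in (t.mirna_direction, t.lncrna_direction, t.mrna_direction)
        ]
    else:
        kept = [t for t in network.triplets if _coregulated(t)]

    out = CeRNANetwork()
    g = out.graph
    for t in kept:
        g.add_node(
            t.mirna_id, role="miRNA", direction=t.mirna_direction
        )
        g.add_node(t.lncrna_id, role="lncRNA", direction=t.lncrna_direction)
        g.add_node(t.mrna_id, role="mRNA", direction=t.mrna_direction)
        g.add_edge(t.mirna_id, t.lncrna_id, n_sites=t.n_sites_lncrna)
        g.add_edge(t.mirna_id, t.mrna_id, n_sites=t.n_sites_mrna)
    out.triplets = kept
    out.validate()
    return out


def network_stats(network: CeRNANetwork) -> dict:
    """Distinct member counts over retained triplets plus per-miRNA degrees."""
    mirnas = sorted({t.mirna_id for t in network.triplets})
    lncrnas = sorted({t.lncrna_id for t in network.triplets})
    mrnas = sorted({t.mrna_id for t in network.triplets})
    degree = {
        m: sum(1 for t in network.triplets if t.mirna_id == m) for m in mirnas
    }
    return {
        "n_mirna": len(mirnas),
        "n_lncrna": len(lncrnas),
        "n_mrna": len(mrnas),
        "n_interactions": len(network.triplets),
        "mirna_degree": degree,
    }


#: Figure-legend colour scheme for the three node roles.
ROLE_COLOURS = {"mRNA": "red", "lncRNA": "green", "miRNA": "orange"}


def export_network(
    network: CeRNANetwork, prefix: str | os.PathLike, formats: Sequence[str] = ("graphml", "edge-tsv")
) -> list[str]:
    """Write GraphML/edge-TSV plus a JSON summary; returns written paths."""
    network.validate()
    g = network.graph.copy()
    for node, data in g.nodes(data=True):
        data["colour"] = ROLE_COLOURS[data["role"]]
    written: list[str] = []
    prefix = str(prefix)
    if "graphml" in formats:
        path = prefix + ".graphml"
        io_formats.write_network(g, path, format="graphml")
        written.append(path)
    if "edge-tsv" in formats:
        path = prefix + ".edges.tsv"
        io_formats.write_network(g, path, format="edge-tsv")
        written.append(path)
    stats = network_stats(network)
    summary_path = prefix + ".summary.json"
    with open(summary_path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(summary_path)
    return written
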