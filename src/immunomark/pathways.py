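"""Pathway collections, interactome merging and pathway activation levels.

A pathway maps each member gene to a discrete activator/repressor role (ARR)
in {-1, -0.5, 0, 0.5, 1}.  The activation level of pathway ``p`` for one
sample is

    PAL_p = sum_n ARR_{n,p} * BTIF_n * ln(CNR_n)

over the pathway's genes, where CNR/BTIF come from
:mod:`immunomark.expression`.  Pathways can be curated or built
algorithmically around a center gene from a merged typed interactome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneActivityVector, compute_activity

logger = logging.getLogger(__name__)

ARR_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: The nine interaction labels recognized on interactome edges.
EDGE_TYPES = (
    "activation",
    "coupling",
    "inhibition",
    "phosphorylation",
    "dissociation",
    "repression",
    "dephosphorylation",
    "binding/association",
    "ubiquitination",
)

#: Default edge-type -> role contribution used when deriving ARR values for
#: gene-centric pathways.  Positive edges push toward activator (+1), negative
#: toward repressor (-1); the remaining association-like types count as weak
#: activation (+0.5).  A gene touched by both positive and negative edges gets
#: 0.  The table is a plain dict so alternatives can be passed in.
DEFAULT_EDGE_ROLES: dict[str, float] = {
    "activation": 1.0,
    "phosphorylation": 1.0,
    "inhibition": -1.0,
    "repression": -1.0,
    "dephosphorylation": -1.0,
    "ubiquitination": -1.0,
    "coupling": 0.5,
    "binding/association": 0.5,
    "dissociation": 0.5,
}

__all__ = [
    "Pathway",
    "PALResult",
    "ARR_VALUES",
    "EDGE_TYPES",
    "DEFAULT_EDGE_ROLES",
    "merge_interactome",
    "build_gene_centric_pathway",
    "compute_pal",
    "pal_matrix",
    "average_profile",
    "read_pathways_json",
    "write_pathways_json",
    "read_interactome_tsv",
    "write_interactome_tsv",
]

Edge = tuple[str, str, str]  # (source, type, target)


@dataclass
class Pathway:
    """Gene -> ARR role mapping with provenance.

    ``origin`` is either ``"curated"`` or ``"gene_centric:<center>"``.
    ``edges`` optionally carries the typed interactions of the pathway so
    collections can be merged into an interactome.
    """

    id: str
    roles: dict[str, float]
    origin: str = "curated"
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValueError(f"pathway {self.id!r} has no member genes")
        for gene, arr in self.roles.items():
            if float(arr) not in ARR_VALUES:
                raise ValueError(
                    f"pathway {self.id!r}: gene {gene!r} has ARR {arr!r}, "
                    f"expected one of {ARR_VALUES}"
                )
        for src, typ, dst in self.edges:
            if typ not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {typ!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.roles)


@dataclass
class PALResult:
    """Activation level of one pathway in one sample."""

    pathway_id: str
    pal: float
    n_contributing: int
    n_missing: int = 0


def merge_interactome(pathways: Sequence[Pathway]) -> nx.MultiDiGraph:
    """Union of pathway edges restricted to the largest connected component.

    Duplicate edges are collapsed on (source, type, target).  Connectivity is
    assessed ignoring edge direction.
    """
    if not pathways:
        raise ValueError("cannot merge an empty pathway collection")
    edges: set[Edge] = set()
    nodes: set[str] = set()
    for p in pathways:
        nodes.update(p.roles)
        edges.update(p.edges)
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(sorted(nodes))
    for src, typ, dst in sorted(edges):
        graph.add_edge(src, dst, type=typ)
    components = list(nx.weakly_connected_components(graph))
    if len(components) > 1:
        keep = max(components, key=lambda c: (len(c), sorted(c)))
        dropped = graph.number_of_nodes() - len(keep)
        logger.info("interactome merge dropped %d node(s) outside the main component", dropped)
        graph = graph.subgraph(keep).copy()
    return graph


def _role_from_types(types: Iterable[str], edge_roles: Mapping[str, float]) -> float:
    contributions = {edge_roles[t] for t in types}
    has_pos = 1.0 in contributions
    has_neg = -1.0 in contributions
    if has_pos and has_neg:
        return 0.0
    if has_pos:
        return 1.0
    if has_neg:
        return -1.0
    return 0.5


def build_gene_centric_pathway(
    net: nx.MultiDiGraph,
    center: str,
    radius: int = 1,
    edge_roles: Mapping[str, float] = DEFAULT_EDGE_ROLES,
) -> Pathway:
    """Build a pathway around ``center`` from the merged interactome.

    The pathway contains the center plus all nodes within ``radius`` hops
    (direction-blind).  Each member's ARR is derived from the types of its
    edges toward the center (edges linking it to any node one hop closer):
    only positive types -> +1, only negative -> -1, mixed -> 0, only
    association-like -> +0.5.  The center itself is an activator (+1).
    """
    if center not in net:
        raise KeyError(f"center gene {center!r} not present in the interactome")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    undirected = net.to_undirected(as_view=False)
    dist = nx.single_source_shortest_path_length(undirected, center, cutoff=radius)
    roles: dict[str, float] = {center: 1.0}
    edges: set[Edge] = set()
    for node, d in dist.items():
        if node == center:
            continue
        inward_types: list[str] = []
        for neighbor in undirected.neighbors(node):
            if dist.get(neighbor, radius + 1) != d - 1:
                continue
            for u, v in ((neighbor, node), (node, neighbor)):
                if net.has_edge(u, v):
                    for key, data in net[u][v].items():
                        inward_types.append(data["type"])
                        edges.add((u, data["type"], v))
        roles[node] = _role_from_types(inward_types, edge_roles)
    return Pathway(
        id=f"gene_centric_{center}",
        roles=roles,
        origin=f"gene_centric:{center}",
        edges=sorted(edges),
    )


def compute_pal(pathway: Pathway, activity: GeneActivityVector) -> PALResult:
    """PAL = sum over pathway genes of ARR * BTIF * ln(CNR).

    Pathway genes absent from the activity vector are skipped; the skip count
    is logged and reported, not raised — clinical FFPE profiles routinely drop
    genes.
    """
    index = pd.Index(activity.gene_ids)
    pal = 0.0
    n_contributing = 0
    n_missing = 0
    positions = index.get_indexer(pd.Index(list(pathway.roles)))
    for (gene, arr), pos in zip(pathway.roles.items(), positions):
        if pos < 0:
            n_missing += 1
            continue
        cnr = activity.cnr[pos]
        if cnr <= 0:
            raise ValueError(f"non-positive CNR for gene {gene!r}")
        flag = activity.btif[pos]
        if flag:
            n_contributing += 1
            pal += arr * np.log(cnr)
    if n_missing:
        logger.info(
            "pathway %s: %d of %d gene(s) missing from the activity vector",
            pathway.id, n_missing, len(pathway.roles),
        )
    if n_contributing == 0:
        pal = 0.0
    return PALResult(pathway.id, float(pal), n_contributing, n_missing)


def pal_matrix(
    pathways: Sequence[Pathway], activities: Mapping[str, GeneActivityVector]
) -> pd.DataFrame:
    """Pathways x samples matrix of PAL values."""
    data = {
        sample: [compute_pal(p, act).pal for p in pathways]
        for sample, act in activities.items()
    }
    return pd.DataFrame(data, index=[p.id for p in pathways])


def average_profile(
    samples: pd.DataFrame,
    controls: ExpressionMatrix,
    alpha: float = 0.05,
    method="zscore",
) -> GeneActivityVector:
    """Activity of the averaged group profile (mean normalized expression
    across the group, computed before CNR)."""
    mean_profile = samples.mean(axis=1)
    mean_profile.name = "group_mean"
    return compute_activity(mean_profile, controls, alpha=alpha, method=method)


# ---------------------------------------------------------------------------
# serialization

def write_pathways_json(pathways: Sequence[Pathway], path) -> None:
    payload = [
        {"id": p.id, "roles": p.roles, "origin": p.origin, "edges": [list(e) for e in p.edges]}
        for p in pathways
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_pathways_json(path) -> list[Pathway]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Pathway(
            id=item["id"],
            roles={g: float(r) for g, r in item["roles"].items()},
            origin=item.get("origin", "curated"),
            edges=[tuple(e) for e in item.get("edges", [])],
        )
        for item in payload
    ]


def write_interactome_tsv(net: nx.MultiDiGraph, path) -> None:
    rows = sorted((u, data["type"], v) for u, v, data in net.edges(data=True))
    pd.DataFrame(rows, columns=["source", "type", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactome_tsv(path) -> nx.MultiDiGraph:
    df = pd.read_csv(path, sep="\t")
    graph = nx.MultiDiGraph()
    for src, typ, dst in df[["source", "type", "target"]].itertuples(index=False):
        if typ not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {typ!r}")
        graph.add_edge(str(src), str(dst), type=typ)
    return graph


def write_pathways_gmt(pathways: Sequence[Pathway], gmt_path, roles_path) -> None:
    """GMT membership plus a sidecar TSV carrying the ARR roles."""
    with open(gmt_path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.id, p.origin, *p.roles]) + "\n")
    rows = [(p.id, g, r) for p in pathways for g, r in p.roles.items()]
    pd.DataFrame(rows, columns=["pathway_id", "gene_id", "arr"]).to_csv(
        roles_path, sep="\t", index=False
    )
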