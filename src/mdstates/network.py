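"""Dynamical-network construction and Girvan-Newman community detection.

One node per residue (ligands may contribute several nodes), edges between
nodes whose residues keep any heavy-atom pair within a distance cutoff for
at least a fraction of frames (4.5 A / 75% defaults), edge weights
-log|C_ij| derived from the cross-correlation matrix.  Communities come
from divisive removal of the highest-betweenness edge (weights as path
lengths); the partition retained is the first maximum of modularity along
the dendrogram, with modularity weighted by |C_ij| (connection strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import Structure, Trajectory
from .dynamics import CorrelationMatrix

__all__ = ["NetworkNode", "DynamicalNetwork", "default_node_map", "build_network", "girvan_newman"]


@dataclass(frozen=True)
class NetworkNode:
    """One network node: an id, its representative atom and member atoms."""

    id: str
    representative_atom: int
    member_atoms: tuple[int, ...]
    resid: int | None = None
    chain: str | None = None


@dataclass
class DynamicalNetwork:
    graph: nx.Graph  # nodes: NetworkNode.id; edge attrs: contact_fraction, correlation, weight
    nodes: list[NetworkNode]
    communities: dict[str, int] | None = None
    modularity: float | None = None


def default_node_map(s: Structure, heavy_only: bool = True) -> list[NetworkNode]:
    """One node per residue, represented by its Calpha (or first heavy atom);
    members are the residue's heavy atoms."""
    nodes = []
    for (chain, resid, resname), idx in s.residues():
        members = tuple(
            i for i in idx if not heavy_only or s.atoms[i].element != "H"
        )
        if not members:
            continue
        rep = next((i for i in members if s.atoms[i].name.strip() == "CA"), members[0])
        nodes.append(NetworkNode(f"{chain}:{resid}", rep, members, resid, chain))
    return nodes


def build_network(
    traj: Trajectory,
    corr: CorrelationMatrix,
    node_map: list[NetworkNode] | None = None,
    d_cut: float = 4.5,
    f_cut: float = 0.75,
    exclude_neighbors: int = 1,
    stride: int = 1,
) -> DynamicalNetwork:
    """Contact-and-correlation network over a trajectory.

    An edge joins two nodes iff any member-atom pair is within ``d_cut`` in
    at least ``f_cut`` of the (strided) frames; sequence neighbours
    (|delta resid| <= ``exclude_neighbors``, same chain) are excluded.  Edge
    weight is -log|C_ij| using the correlation of the representative atoms;
    a zero correlation drops the edge with a warning (infinite weight).

    ``corr`` must hold one row per node, in node order (its selection's
    indices must equal the representative atoms).
    """
    nodes = default_node_map(traj.topology) if node_map is None else node_map
    n = len(nodes)
    reps = np.array([nd.representative_atom for nd in nodes])
    if corr.values.shape != (n, n):
        raise ValueError("correlation matrix does not cover all nodes")
    if not np.array_equal(np.asarray(corr.selection.indices), np.sort(reps)):
        warnings.warn("correlation selection differs from node representative atoms")

    atom_node = {}
    for k, nd in enumerate(nodes):
        for a in nd.member_atoms:
            atom_node[a] = k
    members = np.fromiter(atom_node.keys(), dtype=int)
    owner = np.fromiter(atom_node.values(), dtype=int)

    frames = np.arange(0, traj.n_frames, stride)
    per_frame_keys = []
    for f in frames:
        pts = traj.coords[f][members]
        pairs = cKDTree(pts).query_pairs(d_cut, output_type="ndarray")
        if pairs.size == 0:
            continue
        a, b = owner[pairs[:, 0]], owner[pairs[:, 1]]
        keep = a != b
        per_frame_keys.append(
            np.unique(
                np.minimum(a[keep], b[keep]).astype(np.int64) * n
                + np.maximum(a[keep], b[keep])
            )
        )
    if per_frame_keys:
        all_keys, key_counts = np.unique(np.concatenate(per_frame_keys), return_counts=True)
        counts = {
            (int(k) // n, int(k) % n): int(c) for k, c in zip(all_keys, key_counts)
        }
    else:
        counts = {}

    g = nx.Graph()
    for nd in nodes:
        g.add_node(nd.id)
    nf = frames.size
    for (i, j), c in counts.items():
        if c / nf < f_cut:
            continue
        ni, nj = nodes[i], nodes[j]
        if (
            ni.chain == nj.chain
            and ni.resid is not None
            and nj.resid is not None
            and abs(ni.resid - nj.resid) <= exclude_neighbors
        ):
            continue
        cij = float(corr.values[i, j])
        if not np.isfinite(cij) or abs(cij) == 0.0:
            warnings.warn(f"edge {ni.id}-{nj.id} dropped: |C| = 0 (infinite weight)")
            continue
        g.add_edge(
            ni.id,
            nj.id,
            contact_fraction=c / nf,
            correlation=cij,
            weight=float(-np.log(abs(cij))),
        )
    return DynamicalNetwork(g, nodes)


def girvan_newman(net: DynamicalNetwork) -> DynamicalNetwork:
    """Girvan-Newman community detection on the dynamical network.

    Edges are removed in order of (weighted) edge betweenness, with the
    -log|C| weights acting as path lengths; the returned partition is the
    first strict maximum of |C|-weighted modularity along the divisive
    dendrogram.  Runs on python-igraph's C implementation.
    """
    import igraph as ig

    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    ids = list(g.nodes)
    index = {nid: k for k, nid in enumerate(ids)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    lengths = [g.edges[u, v]["weight"] for u, v in g.edges]
    strengths = [abs(g.edges[u, v]["correlation"]) for u, v in g.edges]
    h = ig.Graph(n=len(ids), edges=edges)
    if not edges:
        communities = {nid: k for k, nid in enumerate(ids)}
        return DynamicalNetwork(g, net.nodes, communities, 0.0)
    # betweenness weights must be positive for shortest paths
    eps = 1e-12
    dendro = h.community_edge_betweenness(
        directed=False, weights=[max(w, eps) for w in lengths]
    )
    n_comp = len(h.connected_components())
    best_membership, best_q = None, -np.inf
    for k in range(n_comp, len(ids) + 1):
        try:
            clustering = dendro.as_clustering(k)
        except Exception:
            continue
        q = h.modularity(clustering.membership, weights=strengths)
        if q > best_q + 1e-12:
            best_q = q
            best_membership = list(clustering.membership)
    communities = {nid: int(best_membership[index[nid]]) for nid in ids}
    return DynamicalNetwork(g, net.nodes, communities, float(best_q))
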