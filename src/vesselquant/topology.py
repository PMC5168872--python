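"""Skeleton graph construction, branch splitting and BFS orientation.

Skeleton points become graph nodes; edges come either from explicit polyline
connectivity, from k-nearest-neighbour linking, or from a fixed-radius
neighbourhood. Junctions are nodes of degree >= 3; a branch is the maximal
path between junction/terminal nodes whose interior nodes have degree 2.
Branches are oriented proximal-to-distal by a deterministic breadth-first
search from a root terminal (ties between neighbours broken by node id).

A healthy Circle of Willis is a one-genus structure, so one independent
cycle in the graph is expected and legal; the cycle count is always
reported.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InvalidRootError,
    LabelCollisionError,
    SkeletonNotConnectedError,
)
from .model import VesselTree, validate_point_set


def build_graph(points, mode: str = "radius", param=None,
                edges: Optional[Sequence] = None) -> VesselTree:
    """Build the undirected skeleton graph over a 3D point cloud.

    Parameters
    ----------
    points
        (n, 3) array of skeleton points (mm).
    mode
        ``"edges"``: use the explicit adjacency in ``edges`` (e.g. polyline
        connectivity from a VTK file).
        ``"knn"``: connect each point to its ``param`` nearest neighbours
        (default 2).
        ``"radius"``: connect points closer than ``param``; default radius
        is 1.5 x the median nearest-neighbour spacing.
    param
        Mode-specific parameter (k or radius).
    edges
        Explicit (i, j) pairs for ``mode="edges"``.

    Raises
    ------
    SkeletonNotConnectedError
        The graph has more than one connected component (the components are
        listed in the message).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if mode == "edges":
        if edges is None:
            raise ValueError("mode='edges' requires explicit adjacency")
        g.add_edges_from((int(i), int(j)) for i, j in edges if i != j)
    elif mode == "knn":
        k = int(param) if param is not None else 2
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)
        for i in range(n):
            for j in idx[i, 1:]:
                g.add_edge(i, int(j))
    elif mode == "radius":
        if param is None:
            tree = cKDTree(pts)
            d, _ = tree.query(pts, k=2)
            param = 1.5 * float(np.median(d[:, 1]))
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(float(param)):
            g.add_edge(int(i), int(j))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    components = list(nx.connected_components(g))
    if len(components) > 1:
        sizes = sorted((len(c) for c in components), reverse=True)
        raise SkeletonNotConnectedError(
            f"skeleton not connected: {len(components)} components "
            f"of sizes {sizes}")
    cycle_count = g.number_of_edges() - g.number_of_nodes() + len(components)
    junctions = sorted(i for i in g.nodes if g.degree[i] >= 3)
    terminals = sorted(i for i in g.nodes if g.degree[i] == 1)
    tree = VesselTree(node_points=pts,
                      edges=sorted(tuple(sorted(e)) for e in g.edges),
                      junctions=junctions, terminals=terminals,
                      cycle_count=cycle_count)
    tree.graph = g
    return tree


def _graph_of(tree: VesselTree) -> nx.Graph:
    g = getattr(tree, "graph", None)
    if g is None:
        g = nx.Graph()
        g.add_nodes_from(range(len(tree.node_points)))
        g.add_edges_from(tree.edges)
        tree.graph = g
    return g


def split_branches(tree: VesselTree) -> list:
    """Split the graph into branches: maximal paths between junction or
    terminal nodes, every interior node of degree 2.

    The junction point is duplicated into each incident branch so that the
    pinned B-spline endpoints of adjacent branches meet exactly. A pure
    cycle of degree-2 nodes becomes one closed branch split at its
    lowest-id node. Every edge lands in exactly one branch; isolated nodes
    are dropped with a warning. Returns the branch point sets (also stored
    on ``tree.branches`` / ``tree.branch_node_ids``).
    """
    g = _graph_of(tree)
    isolated = [i for i in g.nodes if g.degree[i] == 0]
    if isolated:
        warnings.warn(f"dropping {len(isolated)} isolated node(s)",
                      stacklevel=2)
    endpoints = sorted(i for i in g.nodes if g.degree[i] != 2)
    visited_edges = set()
    branch_ids = []

    def edge_key(a: int, b: int) -> tuple:
        return (a, b) if a < b else (b, a)

    for start in endpoints:
        for nb in sorted(g.neighbors(start)):
            if edge_key(start, nb) in visited_edges:
                continue
            path = [start, nb]
            visited_edges.add(edge_key(start, nb))
            while g.degree[path[-1]] == 2 and path[-1] not in endpoints:
                prev, cur = path[-2], path[-1]
                nxt = [x for x in g.neighbors(cur) if x != prev]
                if not nxt:
                    break
                path.append(nxt[0])
                visited_edges.add(edge_key(cur, nxt[0]))
            branch_ids.append(path)

    # components that are pure cycles (all degree 2): split at lowest id
    for comp in nx.connected_components(g):
        comp_edges = {edge_key(a, b) for a, b in g.edges(comp)}
        if comp_edges and not (comp_edges & visited_edges):
            start = min(comp)
            path = [start]
            prev = None
            cur = start
            while True:
                nxt = sorted(x for x in g.neighbors(cur) if x != prev)
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
                visited_edges.add(edge_key(prev, cur))
                if cur == start:
                    break
            branch_ids.append(path)

    branch_ids.sort(key=lambda p: (p[0], p[-1], len(p)))
    tree.branch_node_ids = branch_ids
    node_radii = getattr(tree, "node_radii", None)
    tree.branches = [
        validate_point_set(tree.node_points[ids],
                           radii=(None if node_radii is None
                                  else np.asarray(node_radii)[ids]),
                           branch_label=f"branch_{k}")
        for k, ids in enumerate(branch_ids)
    ]
    return tree.branches


def orient_bfs(tree: VesselTree, root: Optional[int] = None) -> VesselTree:
    """Orient every branch proximal-to-distal by breadth-first search.

    ``root`` should be a terminal node (e.g. the basilar inlet); by default
    the terminal with the lowest z coordinate is used (ties by node id).
    BFS is deterministic: neighbours are visited in node-id order. Branch
    point sequences are reversed where needed so each branch runs from its
    BFS-earlier endpoint to the later one, and ``tree.parent`` records the
    BFS parent of every reached node.
    """
    g = _graph_of(tree)
    if root is None:
        if tree.terminals:
            zs = tree.node_points[tree.terminals, 2]
            root = int(tree.terminals[int(np.argmin(zs))])
        else:
            root = min(g.nodes)
    if root not in g.nodes:
        raise InvalidRootError(f"invalid root {root}")
    order = {root: 0}
    parent = {}
    queue = [root]
    head = 0
    while head < len(queue):
        cur = queue[head]
        head += 1
        for nb in sorted(g.neighbors(cur)):
            if nb not in order:
                order[nb] = len(order)
                parent[nb] = cur
                queue.append(nb)
    tree.root = root
    tree.parent = parent
    if not tree.branch_node_ids:
        split_branches(tree)
    new_ids = []
    new_branches = []
    node_radii = getattr(tree, "node_radii", None)
    for k, ids in enumerate(tree.branch_node_ids):
        if order.get(ids[0], np.inf) > order.get(ids[-1], np.inf):
            ids = list(reversed(ids))
        new_ids.append(ids)
        label = tree.branches[k].branch_label if tree.branches else None
        new_branches.append(validate_point_set(
            tree.node_points[ids],
            radii=(None if node_radii is None
                   else np.asarray(node_radii)[ids]),
            branch_label=label))
    tree.branch_node_ids = new_ids
    tree.branches = new_branches
    return tree


def assign_labels(tree: VesselTree, label_map: dict) -> VesselTree:
    """Attach anatomic labels to branches from a user-supplied map keyed by
    branch index. Unlabeled branches keep auto-names ``branch_k``; unknown
    indices are ignored with a warning; duplicate labels are an error."""
    seen = {}
    for idx, name in label_map.items():
        idx = int(idx)
        if idx < 0 or idx >= tree.n_branches:
            warnings.warn(f"label map index {idx} has no branch; ignored",
                          stacklevel=2)
            continue
        if name in seen:
            raise LabelCollisionError(
                f"label collision: {name!r} assigned to branches "
                f"{seen[name]} and {idx}")
        seen[name] = idx
        tree.labels[idx] = name
        tree.branches[idx].branch_label = name
    for k, b in enumerate(tree.branches):
        if b.branch_label is None:
            b.branch_label = f"branch_{k}"
    return tree
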