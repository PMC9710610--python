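"""Clonal lineage networks: ground truth, inference and topology metrics.

A lineage network is a tree over the unique receptor variants of one
clone, rooted at the unmutated founder receptor.  During simulation the
tree is grown as SHM events create new variants (ground truth); after
simulation the same topology can be inferred from the surviving variant
sequences alone with the pairwise-edit-distance iterative-attachment
algorithm, and the two compared.

Topology metrics: depth (max root-to-leaf edge count), size (non-root
node count), breadth (max node count over non-root depth levels) and the
Sackin index (sum of root-to-leaf depths over all leaves), a standard
tree-imbalance statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import networkx as nx

#: separator between heavy and light chain in a variant's concatenated sequence
CHAIN_SEP = "|"


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit costs) via edlib's NW alignment."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class LineageNode:
    variant_id: int
    seq: str
    parent: int | None  # variant_id of the parent; None for the root
    cell_counts: Counter = field(default_factory=Counter)  # isotype -> alive cells
    historical: bool = False


class LineageNetwork:
    """Rooted tree of unique receptor variants of one clone."""

    def __init__(self, clone_id: int, root_seq: str):
        self.clone_id = clone_id
        self.nodes: dict[int, LineageNode] = {}
        self.children: dict[int, list[int]] = {}
        self._seq_index: dict[str, int] = {}
        self._next_id = 0
        root = LineageNode(variant_id=0, seq=root_seq, parent=None)
        self._add_node(root)

    def _add_node(self, node: LineageNode) -> None:
        self.nodes[node.variant_id] = node
        self.children[node.variant_id] = []
        self._seq_index[node.seq] = node.variant_id
        if node.parent is not None:
            self.children[node.parent].append(node.variant_id)
        self._next_id = max(self._next_id, node.variant_id + 1)

    @property
    def root_id(self) -> int:
        return 0

    @property
    def root_seq(self) -> str:
        return self.nodes[0].seq

    def variant_for_seq(self, seq: str) -> int | None:
        return self._seq_index.get(seq)

    def edges(self) -> list[tuple[int, int]]:
        return [
            (n.parent, n.variant_id) for n in self.nodes.values() if n.parent is not None
        ]

    def depth_of(self, variant_id: int) -> int:
        d = 0
        node = self.nodes[variant_id]
        while node.parent is not None:
            node = self.nodes[node.parent]
            d += 1
        return d

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes.values():
            g.add_node(
                node.variant_id,
                seq=node.seq,
                historical=node.historical,
                cell_counts=dict(node.cell_counts),
            )
        g.add_edges_from(self.edges())
        return g


def record_mutation(
    network: LineageNetwork, parent_variant_id: int, child_seq: str
) -> LineageNode:
    """Register an SHM product as a (possibly pre-existing) variant node.

    Re-mutation onto a sequence already present in the network merges into
    the existing node: unique variants stay unique.
    """
    if parent_variant_id not in network.nodes:
        raise KeyError(f"parent variant {parent_variant_id} not in network")
    existing = network.variant_for_seq(child_seq)
    if existing is not None:
        return network.nodes[existing]
    node = LineageNode(
        variant_id=network._next_id, seq=child_seq, parent=parent_variant_id
    )
    network._add_node(node)
    return node


def infer_network(
    unique_seqs: list[str], germline_seq: str, clone_id: int = -1
) -> LineageNetwork:
    """Reconstruct a lineage tree from sequences alone.

    Nodes are added in ascending order of edit distance to the germline
    (ties broken lexicographically by sequence) and each new node attaches
    to the already-placed node at minimal edit distance (ties: the
    earliest-placed node).  A sequence identical to the germline merges
    into the root.
    """
    net = LineageNetwork(clone_id=clone_id, root_seq=germline_seq)
    order = sorted(
        (s for s in set(unique_seqs) if s != germline_seq),
        key=lambda s: (edit_distance(s, germline_seq), s),
    )
    placed: list[int] = [net.root_id]  # in placement order
    for seq in order:
        best_id, best_d = placed[0], None
        for vid in placed:
            d = edit_distance(seq, net.nodes[vid].seq)
            if best_d is None or d < best_d:
                best_id, best_d = vid, d
        node = LineageNode(variant_id=net._next_id, seq=seq, parent=best_id)
        net._add_node(node)
        placed.append(node.variant_id)
    return net


@dataclass(frozen=True)
class TopologyMetrics:
    depth: int
    size: int
    breadth: int
    sackin: int


def topology_metrics(network: LineageNetwork) -> TopologyMetrics:
    """Depth, size, breadth and Sackin index of a lineage tree.

    The germline root is excluded from size, and the root level from
    breadth; a germline-only network scores (0, 0, 0, 0).
    """
    depths = {network.root_id: 0}
    stack = [network.root_id]
    while stack:
        vid = stack.pop()
        for child in network.children[vid]:
            depths[child] = depths[vid] + 1
            stack.append(child)
    non_root = [v for v in network.nodes if v != network.root_id]
    if not non_root:
        return TopologyMetrics(0, 0, 0, 0)
    leaves = [v for v in network.nodes if not network.children[v] and v != network.root_id]
    level_counts = Counter(depths[v] for v in non_root)
    return TopologyMetrics(
        depth=max(depths.values()),
        size=len(non_root),
        breadth=max(level_counts.values()),
        sackin=sum(depths[v] for v in leaves),
    )


def _spliced_true_edges(true_net: LineageNetwork) -> tuple[set[str], set[tuple[str, str]], bool]:
    """Node sequences and edges of the true network after historical-node
    reduction.

    Historical leaves are pruned recursively (their sequences can never
    appear in the inference input) and historical pass-through nodes of
    degree 2 are spliced out, connecting parent to child.  Returns
    (node seqs, edge seq-pairs, fully_reducible); the root is always kept.
    ``fully_reducible`` is False when a historical node with >= 2 surviving
    children remains — such a topology cannot be recovered from surviving
    sequences alone.
    """
    parent = {v: n.parent for v, n in true_net.nodes.items()}
    children = {v: set(c) for v, c in true_net.children.items()}
    alive_set = {
        v for v, n in true_net.nodes.items() if not n.historical or v == true_net.root_id
    }
    changed = True
    while changed:
        changed = False
        for v in list(parent):
            if v in alive_set or v not in parent:
                continue
            if not children[v]:  # historical leaf: prune
                children[parent[v]].discard(v)
                del parent[v], children[v]
                changed = True
            elif len(children[v]) == 1:  # pass-through: splice
                (child,) = children[v]
                p = parent[v]
                children[p].discard(v)
                children[p].add(child)
                parent[child] = p
                del parent[v], children[v]
                changed = True
    reducible = all(v in alive_set for v in parent)
    seqs = {true_net.nodes[v].seq for v in parent}
    edges = {
        (true_net.nodes[parent[v]].seq, true_net.nodes[v].seq)
        for v in parent
        if parent[v] is not None
    }
    return seqs, edges, reducible


def networks_match(
    true_net: LineageNetwork, inferred_net: LineageNetwork, log: list[str] | None = None
) -> bool:
    """Strict topology agreement between ground truth and inference.

    Nodes are mapped by sequence identity; the true network is reduced over
    its historical nodes (splice degree-2, prune leaves) and the directed
    edge sets must then be identical.
    """

    def note(msg: str) -> None:
        if log is not None:
            log.append(msg)

    true_seqs, true_edges, reducible = _spliced_true_edges(true_net)
    if not reducible:
        note("true network has a branching historical node not recoverable from sequences")
        return False
    inf_seqs = {n.seq for n in inferred_net.nodes.values()}
    if true_seqs != inf_seqs:
        note(
            f"node sets differ: {len(true_seqs - inf_seqs)} only-true, "
            f"{len(inf_seqs - true_seqs)} only-inferred"
        )
        return False
    inf_edges = {
        (inferred_net.nodes[n.parent].seq, n.seq)
        for n in inferred_net.nodes.values()
        if n.parent is not None
    }
    if true_edges != inf_edges:
        note(f"edge sets differ on {len(true_edges ^ inf_edges)} edges")
        return False
    return True
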