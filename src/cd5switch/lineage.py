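"""Intraclonal lineage reconstruction and CD5 tip coloring.

The clone's lineage is approximated by a minimum spanning tree over the
complete Hamming-distance graph of the unique clone sequences, rooted at
the central (most abundant) sequence. For the star-like clusters produced
by intraclonal diversification around one ancestor, the MST attains the
maximum-parsimony tree length; in general it is an upper bound, checked
against a brute-force small-parsimony oracle in tests. Edges are chosen by
Kruskal's algorithm with a deterministic tie-break (weight, then
lexicographic endpoint order), so the tree is input-order invariant.

Tips are classified by the gate(s) each sequence was observed in
(``high_only`` / ``low_only`` / ``both``), mirroring the red/blue/green
coloring of combined-gate phylogenies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .stats import distance_matrix


@dataclass
class LineageTree:
    sequences: list[str]  # unique clone sequences; root first is NOT assumed
    root: str
    parent: dict[str, str | None]  # root maps to None
    children: dict[str, list[str]] = field(repr=False, default_factory=dict)
    weights: dict[str, int] = field(default_factory=dict)  # edge weight above each non-root node

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())


def build_lineage_tree(sequences: list[str], central: str) -> LineageTree:
    """Minimum spanning tree over unique equal-length clone sequences.

    ``central`` must be among the sequences; the tree is rooted there.
    """
    seqs = sorted(set(sequences) | {central})
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("all clone sequences must have equal length")
    n = len(seqs)
    if n == 1:
        return LineageTree([central], central, {central: None}, {central: []}, {})
    D = distance_matrix(seqs)
    # Kruskal with deterministic tie-break: (weight, seq_i, seq_j), i<j lexicographic
    order = sorted(
        ((int(D[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent_uf = list(range(n))

    def find(x: int) -> int:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    n_edges = 0
    for w, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_uf[ri] = rj
            adj[i].append((j, w))
            adj[j].append((i, w))
            n_edges += 1
            if n_edges == n - 1:
                break

    root_idx = seqs.index(central)
    parent: dict[str, str | None] = {central: None}
    children: dict[str, list[str]] = {s: [] for s in seqs}
    weights: dict[str, int] = {}
    stack = [root_idx]
    seen = {root_idx}
    while stack:
        u = stack.pop()
        for v, w in sorted(adj[u]):
            if v in seen:
                continue
            seen.add(v)
            parent[seqs[v]] = seqs[u]
            children[seqs[u]].append(seqs[v])
            weights[seqs[v]] = w
            stack.append(v)
    return LineageTree(seqs, central, parent, children, weights)


def parsimony_score(tree: LineageTree) -> int:
    """Total substitutions implied by the tree (sum of edge weights)."""
    return tree.total_weight


def classify_tips(
    tree: LineageTree, high: set[str], low: set[str]
) -> tuple[dict[str, str], Counter]:
    """Label every node by the gate(s) it was observed in.

    Returns the per-sequence state map and counts per state. A node in
    neither gate indicates an upstream clone-extraction bug and is an error.
    """
    states: dict[str, str] = {}
    for seq in tree.sequences:
        in_h, in_l = seq in high, seq in low
        if in_h and in_l:
            states[seq] = "both"
        elif in_h:
            states[seq] = "high_only"
        elif in_l:
            states[seq] = "low_only"
        else:
            raise ValueError("tree node observed in neither gate; clone extraction mismatch")
    return states, Counter(states.values())


def _node_label(
    seq: str, tree: LineageTree, names: dict[str, str], states: dict[str, str] | None
) -> str:
    label = names[seq]
    if states is not None:
        label += f"|{states[seq]}"
    return label


def export_newick(
    tree: LineageTree,
    names: dict[str, str] | None = None,
    states: dict[str, str] | None = None,
) -> str:
    """Serialize the rooted tree as Newick with Hamming branch lengths.

    Default names: ``central`` for the root, ``v0001``... for the other
    sequences in lexicographic order. When a tip-state map is given, labels
    carry a ``|state`` suffix.
    """
    if names is None:
        others = [s for s in tree.sequences if s != tree.root]
        names = {s: f"v{i + 1:04d}" for i, s in enumerate(sorted(others))}
        names[tree.root] = "central"

    def render(seq: str) -> str:
        label = _node_label(seq, tree, names, states)
        kids = tree.children.get(seq, [])
        inner = f"({','.join(render(c) for c in kids)})" if kids else ""
        length = f":{tree.weights[seq]}" if tree.parent[seq] is not None else ""
        return f"{inner}{label}{length}"

    return render(tree.root) + ";"


def subtree_sequences(tree: LineageTree, seq: str) -> set[str]:
    """All sequences in the subtree rooted at ``seq`` (inclusive)."""
    out, stack = set(), [seq]
    while stack:
        s = stack.pop()
        if s in out:
            continue
        out.add(s)
        stack.extend(tree.children.get(s, []))
    return out


def states_confined_to_subtree(tree: LineageTree, states: dict[str, str], state: str) -> bool:
    """True if all nodes with the given state lie in one proper subtree.

    Used to test the rare-switch signature: under a single founder switch,
    the switched-only tips form one connected sub-lineage of the tree.
    """
    marked = {s for s, st in states.items() if st == state}
    if not marked:
        return True
    for candidate in tree.sequences:
        if candidate == tree.root:
            continue
        if marked <= subtree_sequences(tree, candidate):
            return True
    return False
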