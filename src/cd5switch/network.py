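"""BCR sequence similarity networks.

Vertices are unique sequences sized by read abundance; edges join sequences
that differ by exactly one substitution (equal length, Hamming distance 1 —
indels never create edges); clusters are the connected components. The
dominant connected component is the leukemic clone in a CLL repertoire,
typically carrying the large majority of all reads around one central
(most abundant) sequence.

Edge construction uses masked-position hashing: two equal-length sequences
are Hamming-1 neighbours iff they share exactly one masked k-mer key
(sequence with one position wildcarded), giving O(n*L) construction that is
verified in tests against the brute-force O(n^2) pairwise scan.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .reads import ProcessedSequence


@dataclass
class UniqueSequence:
    sequence: str
    read_count: int
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def cd5_label(self) -> str:
        samples = {s for s, n in self.sample_counts.items() if n > 0}
        if samples == {"high"}:
            return "high"
        if samples == {"low"}:
            return "low"
        if samples >= {"high", "low"}:
            return "both"
        return "unsorted" if samples else "unknown"


@dataclass
class CloneCluster:
    members: list[UniqueSequence]
    central_sequence: str
    total_reads: int
    fraction_of_repertoire: float  # by reads
    fraction_of_vertices: float

    @property
    def member_sequences(self) -> set[str]:
        return {m.sequence for m in self.members}

    def sample_member_sequences(self, sample_id: str) -> set[str]:
        return {
            m.sequence
            for m in self.members
            if m.sample_counts.get(sample_id, 0) > 0
        }


def collapse_unique(processed: list[ProcessedSequence]) -> list[UniqueSequence]:
    """One vertex per distinct sequence; read counts summed and kept per sample."""
    totals: Counter = Counter()
    per_sample: dict[str, Counter] = defaultdict(Counter)
    for p in processed:
        totals[p.sequence] += p.read_count
        per_sample[p.sequence][p.sample_id] += p.read_count
    return [
        UniqueSequence(seq, count, dict(sorted(per_sample[seq].items())))
        for seq, count in sorted(totals.items())
    ]


def hamming1_edges(sequences: list[str]) -> list[tuple[int, int]]:
    """Index pairs of sequences at Hamming distance exactly 1 (equal length).

    Two distinct equal-length sequences share a masked key (one position
    replaced by a wildcard) iff they differ only at that position.
    """
    buckets: dict[tuple[int, int, str], list[int]] = defaultdict(list)
    for idx, seq in enumerate(sequences):
        L = len(seq)
        for pos in range(L):
            buckets[(L, pos, seq[:pos] + seq[pos + 1 :])].append(idx)
    edges = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if sequences[i] != sequences[j]:
                    edges.add((min(i, j), max(i, j)))
    return sorted(edges)


@dataclass
class SequenceNetwork:
    vertices: list[UniqueSequence]
    edges: list[tuple[int, int]]
    clusters: list[list[int]]  # vertex indices, one list per connected component

    @property
    def total_reads(self) -> int:
        return sum(v.read_count for v in self.vertices)

    def cluster_summary(self) -> pd.DataFrame:
        total = self.total_reads
        rows = []
        for cid, members in enumerate(self.clusters):
            reads = sum(self.vertices[i].read_count for i in members)
            central = max(
                members, key=lambda i: (self.vertices[i].read_count, self.vertices[i].sequence)
            )
            # tie on read_count resolved to the lexicographically smallest sequence
            best = self.vertices[central].read_count
            central_seq = min(
                self.vertices[i].sequence for i in members if self.vertices[i].read_count == best
            )
            rows.append(
                {
                    "cluster_id": cid,
                    "n_vertices": len(members),
                    "n_reads": reads,
                    "fraction_reads": reads / total if total else 0.0,
                    "central_sequence": central_seq,
                }
            )
        return pd.DataFrame(rows)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for i, v in enumerate(self.vertices):
            g.add_node(
                i,
                sequence=v.sequence,
                read_count=v.read_count,
                cd5_label=v.cd5_label,
                **{f"reads_{s}": n for s, n in v.sample_counts.items()},
            )
        g.add_edges_from(self.edges)
        nx.write_graphml(g, path)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": self.vertices[i].sequence, "target": self.vertices[j].sequence}
                for i, j in self.edges
            ]
        )


def build_network(vertices: list[UniqueSequence]) -> SequenceNetwork:
    """Assemble the Hamming-1 network and its connected-component clusters."""
    seqs = [v.sequence for v in vertices]
    edges = hamming1_edges(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(len(vertices)))
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    # deterministic ordering: by reads desc, then size desc, then smallest sequence
    def comp_key(members: list[int]):
        reads = sum(vertices[i].read_count for i in members)
        return (-reads, -len(members), min(vertices[i].sequence for i in members))

    comps.sort(key=comp_key)
    return SequenceNetwork(vertices, edges, comps)


def largest_cluster_stats(network: SequenceNetwork) -> CloneCluster:
    """The cluster with the most reads (ties: more vertices, smaller central)."""
    if not network.vertices:
        raise ValueError("empty network has no largest cluster")
    members_idx = network.clusters[0]
    members = [network.vertices[i] for i in members_idx]
    total = sum(m.read_count for m in members)
    best = max(m.read_count for m in members)
    central = min(m.sequence for m in members if m.read_count == best)
    all_reads = network.total_reads
    return CloneCluster(
        members=members,
        central_sequence=central,
        total_reads=total,
        fraction_of_repertoire=total / all_reads,
        fraction_of_vertices=len(members) / len(network.vertices),
    )


def network_from_sized_fasta(path: str | Path) -> SequenceNetwork:
    """Build a network from a FASTA with ``;size=`` annotations."""
    from . import io as _io

    records = _io.read_sized_fasta(path)
    processed = [ProcessedSequence(seq, size, "unsorted") for _name, seq, size in records]
    return build_network(collapse_unique(processed))
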