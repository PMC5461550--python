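"""Stage-2 entry: merge per-library tables, build and collapse the de Bruijn graph.

Per-library sorted frequency tables are multi-way merged (counts for the
same mer summed across libraries) and the k-mer coverage cutoff ``c`` is
applied *before* graph construction: a mer whose summed frequency is below
c never enters the graph.  The same cutoff is applied to the (k+1)-mer
edge table so that edge support is consistent with vertex support.

The graph has one vertex per retained k-mer and a directed edge for every
retained (k+1)-mer whose k-prefix and k-suffix both survived; maximal
nonbranching paths are then collapsed into single sequence-bearing nodes
whose successive constituent k-mers overlap by k-1 characters.  Node ids
are assigned in order of the smallest constituent k-mer code, so repeated
runs are bit-identical.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .kmercount import FrequencyTable, _FAST_K, decode_mers, decode_mer, encode_mer


@dataclass
class AssemblyParams:
    """Tunable parameters of the sequential (assembly) stage.

    k: k-mer length; c: k-mer coverage cutoff; c2: paired-edge cutoff
    (None derives it from dataset size as max(2, total_Gb * c2_per_gb));
    min_graph_len: minimum longest-path length of a retained splicing
    graph; tip_len: dead-end length threshold (None means 2k);
    bubble_max_mismatch: per-branch-pair mismatch allowance for SNP
    bubble merging.
    """

    k: int = 25
    c: int = 3
    c2: Optional[int] = None
    min_graph_len: int = 100
    tip_len: Optional[int] = None
    bubble_max_mismatch: int = 2
    c2_per_gb: float = 20.0
    qmin: int = 15
    k0: int = 12
    rpkm_exclude_empty: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.min_graph_len < 1:
            raise ValueError("min_graph_len must be >= 1")

    @property
    def effective_tip_len(self) -> int:
        return self.tip_len if self.tip_len is not None else 2 * self.k

    def effective_c2(self, total_bases: int) -> int:
        if self.c2 is not None:
            return self.c2
        return max(2, round(total_bases / 1e9 * self.c2_per_gb))


class DBGraph:
    """Collapsed de Bruijn graph of sequence-bearing nodes.

    Backed by a :class:`networkx.DiGraph` with integer node ids and node
    attributes ``seq`` (spelled sequence), ``cov`` (summed k-mer
    frequency) and ``min_code`` (smallest constituent k-mer code, the
    deterministic ordering key).  ``paired`` maps (u, v) node-id pairs to
    paired-edge counts.
    """

    def __init__(self, k: int, g: Optional[nx.DiGraph] = None):
        self.k = k
        self.g = g if g is not None else nx.DiGraph()
        self.paired: dict[tuple[int, int], int] = {}
        self._kmer_index: Optional[dict[int, int]] = None

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def sequence(self, node: int) -> str:
        return self.g.nodes[node]["seq"]

    def coverage(self, node: int) -> int:
        return self.g.nodes[node]["cov"]

    def spellings(self) -> list[str]:
        return sorted(d["seq"] for _, d in self.g.nodes(data=True))

    def copy(self) -> "DBGraph":
        out = DBGraph(self.k, self.g.copy())
        out.paired = dict(self.paired)
        return out

    def invalidate_index(self) -> None:
        self._kmer_index = None

    def kmer_index(self) -> dict[int, int]:
        """Map from k-mer code to the id of the node containing it."""
        if self._kmer_index is None:
            idx: dict[int, int] = {}
            k = self.k
            for node in self.g.nodes:
                seq = self.g.nodes[node]["seq"]
                for i in range(len(seq) - k + 1):
                    window = seq[i : i + k]
                    if "N" in window:
                        continue
                    idx[encode_mer(window)] = node
            self._kmer_index = idx
        return self._kmer_index


def merge_tables(tables: list[FrequencyTable], c: int = 1) -> FrequencyTable:
    """Multi-way merge of same-length tables; drop summed counts < c."""
    if not tables:
        raise ValueError("no tables to merge")
    k_len = tables[0].k_len
    if any(t.k_len != k_len for t in tables):
        raise ValueError("cannot merge tables with different mer lengths")
    if all(t.is_fast for t in tables):
        all_codes = np.concatenate([t.codes for t in tables])
        all_counts = np.concatenate([t.counts for t in tables])
        if all_codes.size == 0:
            return FrequencyTable(k_len, all_codes, all_counts.astype(np.int64))
        uniq, inv = np.unique(all_codes, return_inverse=True)
        sums = np.bincount(inv, weights=all_counts.astype(np.float64))
        sums = np.rint(sums).astype(np.int64)
        keep = sums >= c
        return FrequencyTable(k_len, uniq[keep], sums[keep])
    acc: dict[int, int] = {}
    for t in tables:
        codes = t.codes.tolist() if t.is_fast else t.codes
        for code, cnt in zip(codes, t.counts):
            acc[int(code)] = acc.get(int(code), 0) + int(cnt)
    items = sorted((code, cnt) for code, cnt in acc.items() if cnt >= c)
    codes_l = [c_ for c_, _ in items]
    counts = np.array([n for _, n in items], dtype=np.int64)
    if k_len <= _FAST_K:
        return FrequencyTable(k_len, np.array(codes_l, dtype=np.uint64), counts)
    return FrequencyTable(k_len, codes_l, counts)


def build_graph(kmer_table: FrequencyTable, edge_table: FrequencyTable) -> DBGraph:
    """Collapsed de Bruijn graph from merged, cutoff-filtered tables."""
    k = kmer_table.k_len
    if edge_table.k_len != k + 1:
        raise ValueError("edge table must have mer length k+1")
    n = len(kmer_table)
    raw = nx.DiGraph()
    if kmer_table.is_fast:
        seqs = decode_mers(kmer_table.codes, k)
        codes = kmer_table.codes
    else:
        seqs = [decode_mer(c, k) for c in kmer_table.codes]
        codes = kmer_table.codes
    for i in range(n):
        raw.add_node(i, seq=seqs[i], cov=int(kmer_table.counts[i]), min_code=int(codes[i]))

    suffix_mask = (1 << (2 * k)) - 1
    ecodes = edge_table.codes

    def find(code: int) -> int:
        i = bisect_left(codes, code)
        if i < n and int(codes[i]) == code:
            return i
        return -1

    for j in range(len(edge_table)):
        e = int(ecodes[j])
        iu = find(e >> 2)
        iv = find(e & suffix_mask)
        if iu >= 0 and iv >= 0:
            raw.add_edge(iu, iv)
    out = DBGraph(k, raw)
    return collapse_paths(out)


def _collapse_nx(g: nx.DiGraph, k: int) -> nx.DiGraph:
    """Collapse maximal nonbranching paths; deterministic integer relabel."""
    chain_of: dict[int, tuple[int, int]] = {}  # node -> (chain idx, position)
    chains: list[list[int]] = []
    visited: set[int] = set()

    def is_start(n: int) -> bool:
        if g.in_degree(n) != 1:
            return True
        p = next(g.predecessors(n))
        return p == n or g.out_degree(p) != 1

    for s in sorted(g.nodes):
        if s in visited or not is_start(s):
            continue
        chain = [s]
        visited.add(s)
        cur = s
        while g.out_degree(cur) == 1:
            nxt = next(g.successors(cur))
            if nxt == cur or nxt in visited or g.in_degree(nxt) != 1:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        chains.append(chain)
    # leftover nodes lie on isolated cycles (every in/out degree == 1);
    # break each cycle at its smallest node and keep a self-loop
    for s in sorted(g.nodes):
        if s in visited:
            continue
        chain = [s]
        visited.add(s)
        cur = next(g.successors(s))
        while cur != s:
            chain.append(cur)
            visited.add(cur)
            cur = next(g.successors(cur))
        chains.append(chain)

    for ci, chain in enumerate(chains):
        for pos, node in enumerate(chain):
            chain_of[node] = (ci, pos)

    merged = []
    for chain in chains:
        seq = g.nodes[chain[0]]["seq"]
        cov = g.nodes[chain[0]]["cov"]
        min_code = g.nodes[chain[0]]["min_code"]
        for node in chain[1:]:
            seq += g.nodes[node]["seq"][k - 1 :]
            cov += g.nodes[node]["cov"]
            min_code = min(min_code, g.nodes[node]["min_code"])
        merged.append((min_code, seq, cov))

    order = sorted(range(len(chains)), key=lambda i: (merged[i][0], merged[i][1]))
    new_id = {ci: rank for rank, ci in enumerate(order)}

    h = nx.DiGraph()
    for ci in order:
        min_code, seq, cov = merged[ci]
        h.add_node(new_id[ci], seq=seq, cov=cov, min_code=min_code)
    for u, v in g.edges:
        cu, pu = chain_of[u]
        cv, pv = chain_of[v]
        if cu == cv and pv == pu + 1:
            continue  # internal to a collapsed path
        h.add_edge(new_id[cu], new_id[cv])
    return h


def collapse_paths(graph: DBGraph) -> DBGraph:
    """Collapse maximal nonbranching paths into single nodes (idempotent)."""
    out = DBGraph(graph.k, _collapse_nx(graph.g, graph.k))
    out.paired = dict(graph.paired)
    return out


def write_gfa(graph: DBGraph, path: str) -> None:
    """GFA 1.0 dump of the collapsed graph (inspection only)."""
    k = graph.k
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for node in sorted(graph.g.nodes):
            d = graph.g.nodes[node]
            fh.write(f"S\t{node}\t{d['seq']}\tDP:i:{d['cov']}\n")
        for u, v in sorted(graph.g.edges):
            fh.write(f"L\t{u}\t+\t{v}\t+\t{k - 1}M\n")
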