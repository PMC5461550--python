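"""Graph cleaning: tip removal, SNP bubble merging, paired-edge construction.

Tips are dead-end nodes (in- or out-degree zero, but not whole isolated
components) whose spelled length is below 2k; they are removed
iteratively, with a re-collapse after every sweep, until a fixpoint.

Split-then-merge structures where *all* branches out of a node run
through simple one-in/one-out nodes that immediately reconverge on a
single node, with equal branch lengths and at most a small number of
mismatches per branch pair, are read as SNP/sequencing-error bubbles and
replaced by the highest-coverage branch; successive structures coalesce
into one node through the following re-collapse.

Paired edges: for each mate pair, the node holding the last k-mer of the
forward mate and the node holding the first k-mer of the
reverse-complemented reverse mate define a directed edge u -> v whose
count is incremented; edges with total count >= c2 are retained.  Data
are not strand-specific, so both mutual orientations of a pair are tried
and ties resolve to the lexicographically smaller (u, v).
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

from .dbg import DBGraph, collapse_paths
from .kmercount import encode_mer, revcomp
from .readio import Library


def remove_tips(graph: DBGraph, tip_len: Optional[int] = None) -> DBGraph:
    """Iteratively remove dead ends shorter than tip_len (default 2k)."""
    limit = tip_len if tip_len is not None else 2 * graph.k
    cur = graph
    while True:
        g = cur.g
        tips = [
            n
            for n in g.nodes
            if (g.in_degree(n) == 0) != (g.out_degree(n) == 0)
            and len(g.nodes[n]["seq"]) < limit
        ]
        if not tips:
            return cur
        g2 = g.copy()
        g2.remove_nodes_from(tips)
        nxt = DBGraph(cur.k, g2)
        cur = collapse_paths(nxt)
        cur.paired = dict(graph.paired)


def _hamming_within(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    bad = 0
    for x, y in zip(a, b):
        if x != y:
            bad += 1
            if bad > limit:
                return False
    return True


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def merge_snp_bubbles(graph: DBGraph, max_mismatch: int = 2) -> DBGraph:
    """Collapse equal-length low-mismatch bubbles to their best branch.

    The surviving branch is the one with the highest k-mer coverage (ties
    broken by canonical sequence so that a graph and its reverse
    complement are simplified symmetrically).  Branches of different
    lengths are left untouched: they are candidate alternative splicing.
    """
    cur = graph
    while True:
        g = cur.g
        removed: set[int] = set()
        for s in sorted(g.nodes):
            if s in removed:
                continue
            outs = [b for b in g.successors(s) if b != s]
            if len(outs) < 2 or len(outs) != g.out_degree(s):
                continue
            if any(b in removed for b in outs):
                continue
            ok = True
            target = None
            for b in outs:
                if g.in_degree(b) != 1 or g.out_degree(b) != 1:
                    ok = False
                    break
                t = next(g.successors(b))
                if t == b or t == s or t in outs:
                    ok = False
                    break
                if target is None:
                    target = t
                elif t != target:
                    ok = False
                    break
            if not ok or target is None:
                continue
            seqs = [g.nodes[b]["seq"] for b in outs]
            if len({len(q) for q in seqs}) != 1:
                continue
            if not all(
                _hamming_within(a, b, max_mismatch)
                for i, a in enumerate(seqs)
                for b in seqs[i + 1 :]
            ):
                continue
            best = max(
                outs,
                key=lambda b: (g.nodes[b]["cov"], _rev_key(_canonical(g.nodes[b]["seq"]))),
            )
            for b in outs:
                if b != best:
                    removed.add(b)
        if not removed:
            return cur
        g2 = g.copy()
        g2.remove_nodes_from(removed)
        nxt = DBGraph(cur.k, g2)
        cur = collapse_paths(nxt)
        cur.paired = dict(graph.paired)


class _rev_key:
    """Orders strings descending under max(), i.e. picks the smallest."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_rev_key") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _rev_key) and self.s == other.s


def _anchor(index: dict[int, int], read: str, k: int, last: bool) -> Optional[int]:
    if len(read) < k:
        return None
    window = read[-k:] if last else read[:k]
    if "N" in window:
        return None
    return index.get(encode_mer(window))


def count_paired(
    graph: DBGraph, libraries: Union[Library, Iterable[Library]]
) -> tuple[dict[tuple[int, int], int], int]:
    """Raw paired-edge counts over all mate pairs, plus anchor-failure tally."""
    if isinstance(libraries, Library):
        libraries = [libraries]
    index = graph.kmer_index()
    k = graph.k
    counts: dict[tuple[int, int], int] = {}
    failures = 0
    for lib in libraries:
        if not lib.paired:
            continue
        for r1, r2 in lib.pairs():
            cands = []
            for fwd, rev in ((r1.sequence, r2.sequence), (r2.sequence, r1.sequence)):
                u = _anchor(index, fwd, k, last=True)
                v = _anchor(index, revcomp(rev), k, last=False)
                if u is not None and v is not None and u != v:
                    cands.append((u, v))
            if not cands:
                failures += 1
                continue
            uv = min(cands)
            counts[uv] = counts.get(uv, 0) + 1
    return counts, failures


def add_paired_edges(
    graph: DBGraph,
    libraries: Union[Library, Iterable[Library]],
    c2: int,
) -> DBGraph:
    """Attach paired edges with count >= c2 to the graph (in place)."""
    counts, failures = count_paired(graph, libraries)
    graph.paired = {uv: n for uv, n in sorted(counts.items()) if n >= c2}
    graph.paired_anchor_failures = failures
    return graph
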