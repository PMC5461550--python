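"""Decomposition of the cleaned graph into acyclic per-gene splicing graphs.

Cyclic strongly connected components mark tangled repeat regions, and
weakly connected components that contain both a node and its reverse
complement mark forward-backward tangles (an artifact of non-strand-
specific data).  Every node inside either structure is emitted as a
singleton splicing graph with its junction information discarded; after
those nodes are removed, each remaining weakly connected component is an
acyclic splicing graph whose nodes approximate exonic segments and whose
edges are splice junctions.

Junction adjustment then removes the k-1 de Bruijn overlap exactly once
per edge so that every spelled path contains each nucleotide once, making
junction locations precise where the topology allows; nodes whose
sequence is fully consumed become empty nodes (isoforms that skip a
segment).  Exactly one of the two possible orientations of each graph is
retained, and only graphs whose longest path is at least ``min_graph_len``
nucleotides (default 100) survive.  RPKM values are attached to nodes
*before* adjustment, so they reflect the original coverage of a branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .dbg import AssemblyParams, DBGraph
from .kmercount import revcomp


@dataclass
class SGNode:
    """One node of a splicing graph.

    ``seq`` is the junction-adjusted sequence (possibly empty), ``pre_seq``
    the pre-adjustment spelling and ``orig_len`` its length (the RPKM
    length denominator).  ``trim_prefix``/``trim_suffix`` record which k-1
    overlaps the adjustment removed from this node.
    """

    nid: int
    seq: str
    pre_seq: str
    orig_len: int
    rpkm: dict[str, float] = field(default_factory=dict)
    reads: dict[str, int] = field(default_factory=dict)
    min_code: int = 0
    trim_prefix: bool = False
    trim_suffix: bool = False
    unadjusted: bool = False


@dataclass
class SplicingGraph:
    """One acyclic component: a single gene's alternatively spliced variants."""

    id: int
    k: int
    nodes: list[SGNode] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)
    paired: dict[tuple[int, int], int] = field(default_factory=dict)
    singleton: bool = False

    def node(self, nid: int) -> SGNode:
        return self._by_id[nid]

    @property
    def _by_id(self) -> dict[int, SGNode]:
        return {n.nid: n for n in self.nodes}

    def nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.nid)
        g.add_edges_from(self.edges)
        return g


@dataclass
class Junction:
    """2k-length signature spanning one splice junction (edge)."""

    edge: tuple[int, int]
    signature: Optional[str]


# ---------------------------------------------------------------------------
# tangle detection


def _nx_of(graph) -> nx.DiGraph:
    return graph.g if isinstance(graph, DBGraph) else graph


def find_sccs(graph) -> list[tuple[set[int], bool]]:
    """Strongly connected components, each flagged cyclic or trivial.

    A component is cyclic if it has more than one node or a self-loop.
    Accepts a :class:`DBGraph` or a bare networkx DiGraph.
    """
    g = _nx_of(graph)
    out = []
    for comp in nx.strongly_connected_components(g):
        comp = set(comp)
        cyclic = len(comp) > 1 or any(g.has_edge(n, n) for n in comp)
        out.append((comp, cyclic))
    return out


def find_fb_tangles(graph: DBGraph) -> list[set[int]]:
    """Weak components containing a node together with its reverse complement."""
    g = graph.g
    flagged = []
    for comp in nx.weakly_connected_components(g):
        comp = set(comp)
        seqs = {g.nodes[n]["seq"] for n in comp}
        if any(revcomp(s) in seqs for s in seqs):
            flagged.append(comp)
    return flagged


# ---------------------------------------------------------------------------
# extraction


def _component_key(seqs: list[str]) -> tuple[str, ...]:
    return tuple(sorted(seqs))


def _keep_orientation(seqs: list[str]) -> bool:
    """Deterministic orientation rule: keep the component whose sorted node
    sequences are lexicographically <= those of its reverse complement."""
    return _component_key(seqs) <= _component_key([revcomp(s) for s in seqs])


def _build_sg(
    dbg: DBGraph, nodes: Iterable[int], singleton: bool, k: int
) -> SplicingGraph:
    g = dbg.g
    nodes = sorted(nodes, key=lambda n: (g.nodes[n]["min_code"], g.nodes[n]["seq"]))
    nid_of = {n: i + 1 for i, n in enumerate(nodes)}
    sg = SplicingGraph(id=0, k=k, singleton=singleton)
    for n in nodes:
        d = g.nodes[n]
        sg.nodes.append(
            SGNode(
                nid=nid_of[n],
                seq=d["seq"],
                pre_seq=d["seq"],
                orig_len=len(d["seq"]),
                rpkm=dict(d.get("rpkm", {})),
                reads=dict(d.get("reads", {})),
                min_code=d["min_code"],
            )
        )
    if not singleton:
        for u, v in g.edges:
            if u in nid_of and v in nid_of:
                sg.edges.append((nid_of[u], nid_of[v]))
        sg.edges.sort()
        for (u, v), cnt in sorted(dbg.paired.items()):
            if u in nid_of and v in nid_of:
                sg.paired[(nid_of[u], nid_of[v])] = cnt
    return sg


def extract_splicing_graphs(dbg: DBGraph, params: AssemblyParams) -> list[SplicingGraph]:
    """Full decomposition: tangle removal, orientation, adjustment, filter."""
    g = dbg.g
    k = dbg.k
    cyclic_nodes: set[int] = set()
    for comp, cyclic in find_sccs(dbg):
        if cyclic:
            cyclic_nodes |= comp
    fb_nodes: set[int] = set()
    for comp in find_fb_tangles(dbg):
        fb_nodes |= comp
    removed = cyclic_nodes | fb_nodes

    graphs: list[SplicingGraph] = []

    # singleton graphs from tangles, one orientation per sequence pair
    best_singleton: dict[str, int] = {}
    for n in sorted(removed):
        seq = g.nodes[n]["seq"]
        canon = min(seq, revcomp(seq))
        prev = best_singleton.get(canon)
        # prefer the node whose own sequence is the smaller orientation
        if prev is None or seq < g.nodes[prev]["seq"]:
            best_singleton[canon] = n
    for canon in sorted(best_singleton):
        n = best_singleton[canon]
        graphs.append(_build_sg(dbg, [n], singleton=True, k=k))

    rest = g.subgraph(set(g.nodes) - removed)
    for comp in nx.weakly_connected_components(rest):
        comp = set(comp)
        sub = rest.subgraph(comp)
        if not nx.is_directed_acyclic_graph(sub):
            raise RuntimeError(
                "residual cycle after tangle removal: SCC bookkeeping bug"
            )
        seqs = [g.nodes[n]["seq"] for n in comp]
        if not _keep_orientation(seqs):
            continue
        graphs.append(_build_sg(dbg, comp, singleton=False, k=k))

    kept = []
    for sg in graphs:
        adjust_junctions(sg, k)
        if longest_path(sg) >= params.min_graph_len:
            kept.append(sg)
    kept.sort(key=lambda sg: min(n.min_code for n in sg.nodes))
    for i, sg in enumerate(kept):
        sg.id = i + 1
    return kept


# ---------------------------------------------------------------------------
# junction adjustment


def adjust_junctions(sg: SplicingGraph, k: int) -> SplicingGraph:
    """Remove the k-1 overlap exactly once per edge (in place).

    Default: a node with incoming edges cedes its (k-1)-prefix.  At a
    merge node (multiple in-edges) whose predecessors all have out-degree
    1 and enough remaining sequence, the overlap is instead ceded from the
    predecessors' suffix side: the merge node keeps its prefix, junction
    boundaries land at their precise locations, and short bridge arms can
    be fully consumed (empty nodes).  Nodes with both multiple in- and
    multiple out-edges keep the default prefix trim and are marked
    unadjusted.
    """
    g = sg.nx()
    by_id = sg._by_id
    order = list(nx.topological_sort(g))
    trim_p: dict[int, bool] = {}
    trim_s: dict[int, bool] = {n: False for n in by_id}
    for w in order:
        preds = list(g.predecessors(w))
        if len(preds) >= 2 and all(
            g.out_degree(p) == 1
            and p != w
            and by_id[p].orig_len - (k - 1) * trim_p.get(p, False) >= k - 1
            for p in preds
        ):
            trim_p[w] = False
            for p in preds:
                trim_s[p] = True
        else:
            trim_p[w] = bool(preds)
    for n in sg.nodes:
        start = (k - 1) if trim_p.get(n.nid, False) else 0
        end = n.orig_len - ((k - 1) if trim_s[n.nid] else 0)
        n.seq = n.pre_seq[start:end]
        n.trim_prefix = trim_p.get(n.nid, False)
        n.trim_suffix = trim_s[n.nid]
        n.unadjusted = g.in_degree(n.nid) > 1 and g.out_degree(n.nid) > 1
    return sg


def longest_path(sg: SplicingGraph) -> int:
    """Longest spelled path length (nt) over adjusted node lengths."""
    g = sg.nx()
    by_id = sg._by_id
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("splicing graph contains a cycle") from exc
    best: dict[int, int] = {}
    for n in order:
        incoming = [best[p] for p in g.predecessors(n)]
        best[n] = len(by_id[n].seq) + (max(incoming) if incoming else 0)
    return max(best.values()) if best else 0


# ---------------------------------------------------------------------------
# junction signatures


def _gather_left(sg: SplicingGraph, g: nx.DiGraph, nid: int, need: int) -> str:
    """Adjusted spelling ending at nid's right boundary, up to need chars.

    Walks back through unique predecessors; stops (possibly short) at an
    ambiguous branch or a source node.
    """
    acc = sg.node(nid).seq
    cur = nid
    while len(acc) < need:
        preds = list(g.predecessors(cur))
        if len(preds) != 1:
            break
        cur = preds[0]
        acc = sg.node(cur).seq + acc
    return acc[-need:] if len(acc) > need else acc


def _gather_right(sg: SplicingGraph, g: nx.DiGraph, nid: int, need: int) -> str:
    acc = sg.node(nid).seq
    cur = nid
    while len(acc) < need:
        succs = list(g.successors(cur))
        if len(succs) != 1:
            break
        cur = succs[0]
        acc = acc + sg.node(cur).seq
    return acc[:need]


def junction_signatures(sg: SplicingGraph, k: Optional[int] = None) -> list[Junction]:
    """2k-length junction signature per edge: the k nucleotides on either
    side of the adjusted node boundary, extended through unique neighbours
    when a node's adjusted sequence is shorter than k.  Ambiguous or
    exhausted extensions yield signature None (unavailable)."""
    k = k if k is not None else sg.k
    g = sg.nx()
    out = []
    for u, v in sg.edges:
        left = _gather_left(sg, g, u, k)
        right = _gather_right(sg, g, v, k)
        if len(left) < k or len(right) < k:
            out.append(Junction((u, v), None))
        else:
            out.append(Junction((u, v), left[-k:] + right[:k]))
    return out


def junction_contexts(
    sg: SplicingGraph, k: Optional[int] = None
) -> list[tuple[tuple[int, int], str, int]]:
    """Per edge: (edge, spelled context around the boundary, boundary offset).

    The context holds up to 2k adjusted nucleotides on either side of the
    node boundary, for occurrence-based matching of junction windows.
    """
    k = k if k is not None else sg.k
    g = sg.nx()
    out = []
    for u, v in sg.edges:
        left = _gather_left(sg, g, u, 2 * k)
        right = _gather_right(sg, g, v, 2 * k)
        out.append(((u, v), left + right, len(left)))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def signature_matches(sig: str, truth: str, max_mismatch: int = 3) -> bool:
    """Orientation-agnostic comparison of two equal-length signatures."""
    if len(sig) != len(truth):
        return False
    return (
        _hamming(sig, truth) <= max_mismatch
        or _hamming(revcomp(sig), truth) <= max_mismatch
    )


def _occurs_spanning(context: str, boundary: int, window: str, max_mismatch: int) -> bool:
    L = len(window)
    lo = max(0, boundary - L + 1)
    hi = min(len(context) - L, boundary - 1)
    for i in range(lo, hi + 1):
        if _hamming(context[i : i + L], window) <= max_mismatch:
            return True
    return False


def window_spans_junction(
    context: str, boundary: int, window: str, max_mismatch: int = 3
) -> bool:
    """True if the 2k window occurs in the context, spanning the boundary,
    with at most max_mismatch mismatches, in either orientation.

    Occurrence-based rather than position-rigid: a junction whose graph
    boundary sits a few bases off the annotated splice site (because the
    alternative exons happen to share their first or last bases) still
    matches as long as the annotated window spans the boundary.
    """
    return _occurs_spanning(context, boundary, window, max_mismatch) or _occurs_spanning(
        context, boundary, revcomp(window), max_mismatch
    )


def score_junctions(
    graphs: Iterable[SplicingGraph],
    truth_windows: Iterable[str],
    k: Optional[int] = None,
    max_mismatch: int = 3,
) -> tuple[float, float]:
    """Junction (sensitivity, specificity) against annotated 2k windows.

    Sensitivity: fraction of truth windows found spanning some assembly
    junction; specificity: fraction of assembly junctions whose boundary
    is spanned by some truth window.  Up to ``max_mismatch`` mismatches,
    either orientation.
    """
    contexts = []
    for sg in graphs:
        contexts.extend(junction_contexts(sg, k))
    truth = sorted(set(truth_windows))
    if truth:
        sens = sum(
            any(window_spans_junction(ctx, b, t, max_mismatch) for _, ctx, b in contexts)
            for t in truth
        ) / len(truth)
    else:
        sens = float("nan")
    if contexts:
        spec = sum(
            any(window_spans_junction(ctx, b, t, max_mismatch) for t in truth)
            for _, ctx, b in contexts
        ) / len(contexts)
    else:
        spec = float("nan")
    return sens, spec


def to_dot(sg: SplicingGraph) -> str:
    """DOT export of one splicing graph (node label: id, adjusted length)."""
    lines = [f"digraph g{sg.id} {{"]
    for n in sg.nodes:
        lines.append(f'  n{n.nid} [label="n{n.nid}\\n{len(n.seq)} nt"];')
    for u, v in sg.edges:
        lines.append(f"  n{u} -> n{v};")
    for (u, v), cnt in sorted(sg.paired.items()):
        lines.append(f'  n{u} -> n{v} [style=dashed, label="{cnt}"];')
    lines.append("}")
    return "\n".join(lines)
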