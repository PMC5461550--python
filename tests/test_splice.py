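"""SCC/tangle detection, splicing-graph extraction, junction adjustment."""

import networkx as nx
import numpy as np
import pytest

from spliceasm.dbg import AssemblyParams, DBGraph
from spliceasm.kmercount import revcomp
from spliceasm.splice import (
    SGNode,
    SplicingGraph,
    adjust_junctions,
    extract_splicing_graphs,
    find_fb_tangles,
    find_sccs,
    junction_signatures,
    longest_path,
    score_junctions,
    signature_matches,
)

from .conftest import graph_from_seqs, rand_seq


def brute_force_sccs(g: nx.DiGraph) -> set[frozenset]:
    """Pairwise-reachability oracle, independent of library SCC code."""
    reach = {n: set(nx.descendants(g, n)) | {n} for n in g.nodes}
    comps = set()
    for n in g.nodes:
        comps.add(frozenset(m for m in reach[n] if n in reach[m]))
    return comps


def test_scc_examples():
    g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    g.add_node("d")
    result = {frozenset(comp): cyclic for comp, cyclic in find_sccs(g)}
    assert result == {frozenset("abc"): True, frozenset("d"): False}
    dag = nx.DiGraph([(1, 2), (2, 3), (1, 3)])
    assert all(not cyclic for _, cyclic in find_sccs(dag))
    loop = nx.DiGraph([(1, 1)])
    assert find_sccs(loop) == [({1}, True)]


def test_scc_matches_bruteforce_on_random_graphs(rng):
    for _ in range(30):
        n = int(rng.integers(2, 30))
        g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)), directed=True)
        ours = {frozenset(comp) for comp, _ in find_sccs(g)}
        assert ours == brute_force_sccs(g)


def _dbg_from_nodes(k, seqs, edges):
    g = nx.DiGraph()
    for i, s in enumerate(seqs):
        g.add_node(i, seq=s, cov=10 * len(s), min_code=i)
    g.add_edges_from(edges)
    return DBGraph(k, g)


def test_fb_tangle_detection(rng):
    s = rand_seq(rng, 40)
    flagged = find_fb_tangles(_dbg_from_nodes(15, [s, revcomp(s)], [(0, 1)]))
    assert flagged == [{0, 1}]
    # reverse complement in a *separate* component: not a tangle
    assert find_fb_tangles(_dbg_from_nodes(15, [s, revcomp(s)], [])) == []
    pal = "ACGT" * 5  # revcomp(pal) == pal
    assert revcomp(pal) == pal
    assert find_fb_tangles(_dbg_from_nodes(15, [pal], [])) == [{0}]


def test_cyclic_scc_nodes_become_singletons(rng):
    k = 15
    seqs = [rand_seq(rng, 160), rand_seq(rng, 160), rand_seq(rng, 80)]
    dbg = _dbg_from_nodes(k, seqs, [(0, 1), (1, 0), (1, 2)])
    graphs = extract_splicing_graphs(dbg, AssemblyParams(k=k, c=1))
    assert all(sg.singleton for sg in graphs)
    # the cycle members are emitted alone; the 80-nt downstream node passes
    # the 100-nt filter only if long enough (it is not)
    lens = sorted(len(sg.nodes[0].pre_seq) for sg in graphs)
    assert lens == [160, 160]


def test_component_below_100nt_filtered(rng):
    g = graph_from_seqs([rand_seq(rng, 80)], 15, read_len=80, step=1)
    assert extract_splicing_graphs(g, AssemblyParams(k=15, c=1)) == []


def test_exon_skip_component_extraction(rng):
    k = 15
    E1, E2, E3 = rand_seq(rng, 150), rand_seq(rng, 90), rand_seq(rng, 150)
    g = graph_from_seqs([E1 + E2 + E3, E1 + E3], k, read_len=60, step=3)
    graphs = extract_splicing_graphs(g, AssemblyParams(k=k, c=1))
    assert len(graphs) == 1  # one orientation of one branch-reconverge component
    sg = graphs[0]
    gx = sg.nx()
    branch = [n for n in gx.nodes if gx.out_degree(n) == 2]
    merge = [n for n in gx.nodes if gx.in_degree(n) == 2]
    assert branch and merge


def test_orientation_selection_is_deterministic(rng):
    k = 15
    seqs = [rand_seq(rng, 200) for _ in range(3)]
    a = extract_splicing_graphs(graph_from_seqs(seqs, k), AssemblyParams(k=k, c=1))
    b = extract_splicing_graphs(graph_from_seqs(seqs, k), AssemblyParams(k=k, c=1))
    assert [(sg.id, [n.seq for n in sg.nodes]) for sg in a] == [
        (sg.id, [n.seq for n in sg.nodes]) for sg in b
    ]
    # exactly one orientation emitted per component
    all_seqs = [n.seq for sg in a for n in sg.nodes]
    assert len(all_seqs) == 3
    for s in all_seqs:
        assert revcomp(s) not in all_seqs or s == revcomp(s)


def _sg(k, seqs, edges, adjust=True):
    nodes = [
        SGNode(nid=i + 1, seq=s, pre_seq=s, orig_len=len(s), min_code=i)
        for i, s in enumerate(seqs)
    ]
    sg = SplicingGraph(id=1, k=k, nodes=nodes, edges=edges)
    if adjust:
        adjust_junctions(sg, k)
    return sg


def test_adjust_linear_chain_conserves_spelling(rng):
    k = 15
    a = rand_seq(rng, 60)
    b_over = a[-(k - 1) :] + rand_seq(rng, 40)
    sg = _sg(k, [a, b_over], [(1, 2)])
    assert sg.node(1).seq == a
    assert sg.node(2).seq == b_over[k - 1 :]
    assert sg.node(1).seq + sg.node(2).seq == a + b_over[k - 1 :]


def test_adjust_single_node_unchanged(rng):
    sg = _sg(15, [rand_seq(rng, 50)], [])
    assert sg.node(1).seq == sg.node(1).pre_seq


def test_skip_bridge_node_becomes_empty(rng):
    """A 2k-2 bridge arm (pure junction-spanning node) is fully consumed."""
    k = 15
    E1, E2, E3 = rand_seq(rng, 100), rand_seq(rng, 60), rand_seq(rng, 100)
    A = E1
    B = E1[-(k - 1) :] + E2 + E3[: k - 1]
    D = E1[-(k - 1) :] + E3[: k - 1]  # skip arm, length 2k-2
    C = E3
    sg = _sg(k, [A, B, D, C], [(1, 2), (1, 3), (2, 4), (3, 4)])
    assert sg.node(3).seq == ""
    assert sg.node(2).seq == E2
    assert sg.node(4).seq == E3
    # spelling conservation along both isoform paths
    assert sg.node(1).seq + sg.node(2).seq + sg.node(4).seq == E1 + E2 + E3
    assert sg.node(1).seq + sg.node(3).seq + sg.node(4).seq == E1 + E3


def test_doubly_branching_node_marked_unadjusted(rng):
    k = 15
    mid = rand_seq(rng, 80)
    seqs = [rand_seq(rng, 60), rand_seq(rng, 60),
            mid, rand_seq(rng, 60), rand_seq(rng, 60)]
    sg = _sg(k, seqs, [(1, 3), (2, 3), (3, 4), (3, 5)])
    assert sg.node(3).unadjusted


def test_longest_path_diamond():
    k = 15
    sg = _sg(
        k,
        ["A" * 40, "C" * 110, "G" * 60, "T" * 40],
        [(1, 2), (1, 3), (2, 4), (3, 4)],
        adjust=False,
    )
    assert longest_path(sg) == 190
    # an empty node on a path contributes nothing
    sg.node(2).seq = ""
    assert longest_path(sg) == 140


def test_longest_path_rejects_cycles():
    sg = _sg(15, ["A" * 40, "C" * 40], [(1, 2), (2, 1)], adjust=False)
    with pytest.raises(ValueError, match="cycle"):
        longest_path(sg)


def test_junction_signature_definitional(rng):
    k = 15
    a = rand_seq(rng, 60)
    b = a[-(k - 1) :] + rand_seq(rng, 40)
    sg = _sg(k, [a, b], [(1, 2)])
    (j,) = junction_signatures(sg, k)
    assert j.signature == a[-k:] + b[k - 1 : 2 * k - 1]
    assert len(j.signature) == 2 * k


def test_signature_mismatch_tolerance(rng):
    k = 15
    sig = rand_seq(rng, 2 * k)
    two_off = "".join(
        ("A" if c != "A" else "C") if i in (3, 17) else c for i, c in enumerate(sig)
    )
    assert signature_matches(two_off, sig, max_mismatch=3)
    four_off = "".join(
        ("A" if c != "A" else "C") if i in (3, 9, 17, 24) else c
        for i, c in enumerate(sig)
    )
    assert not signature_matches(four_off, sig, max_mismatch=3)


def test_big_tangle_on_repeat_sharing_genes(rng):
    """Genes sharing a repeat collapse into one large tangled component."""
    k = 15
    repeat = rand_seq(rng, 120)
    seqs = [rand_seq(rng, 150) + repeat + rand_seq(rng, 150) for _ in range(4)]
    seqs += [rand_seq(rng, 250) for _ in range(4)]
    g = graph_from_seqs(seqs, k, read_len=80, step=4)
    comps = sorted(len(c) for c in nx.weakly_connected_components(g.g))
    assert comps[-1] > np.median(comps)
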