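"""Tip removal, SNP bubble merging, and paired-edge construction."""

import networkx as nx
import pytest

from spliceasm.dbg import DBGraph, build_graph, merge_tables
from spliceasm.kmercount import count_library, revcomp
from spliceasm.readio import Library
from spliceasm.simplify import (
    add_paired_edges,
    count_paired,
    merge_snp_bubbles,
    remove_tips,
)

from .conftest import graph_from_seqs, rand_seq, tile_reads

K = 15


def _tip_fixture(rng, extra_len):
    """Backbone transcript plus one erroneous read producing a dead-end
    branch of spelled length extra_len + K - 1."""
    T = rand_seq(rng, 400)
    M = rand_seq(rng, extra_len)
    err = T[150:200] + M
    reads = tile_reads(T, 80, 8) + [err]
    lib = Library.from_sequences("t", reads)
    tk, tk1 = count_library(lib, K)
    return T, build_graph(merge_tables([tk], 1), merge_tables([tk1], 1))


def test_tip_below_2k_removed(rng):
    T, g = _tip_fixture(rng, K)  # branch length 2K-1
    cleaned = remove_tips(g, 2 * K)
    assert cleaned.spellings() == sorted([T, revcomp(T)])


def test_tip_at_2k_retained(rng):
    T, g = _tip_fixture(rng, K + 1)  # branch length exactly 2K
    cleaned = remove_tips(g, 2 * K)
    assert len(cleaned) == len(g)


def test_isolated_short_node_is_not_a_tip(rng):
    seq = rand_seq(rng, 30)  # single node < 2K but a whole component
    g = graph_from_seqs([seq], K, read_len=30, step=1)
    assert len(remove_tips(g, 2 * K)) == len(g)


def test_tip_removal_reaches_fixpoint_deterministically(rng):
    _, g = _tip_fixture(rng, K)
    a = remove_tips(g, 2 * K)
    b = remove_tips(g.copy(), 2 * K)
    assert a.spellings() == b.spellings()


def _snp_fixture(rng, n_alleles=2, ratio=(3, 1)):
    base = rand_seq(rng, 300)
    seqs = [base]
    pos = 150
    alts = [b for b in "ACGT" if b != base[pos]]
    for i in range(n_alleles - 1):
        seqs.append(base[:pos] + alts[i] + base[pos + 1 :])
    reads = []
    for s, mult in zip(seqs, ratio):
        reads += tile_reads(s, 70, 5) * mult
    lib = Library.from_sequences("s", reads)
    tk, tk1 = count_library(lib, K)
    g = build_graph(merge_tables([tk], 1), merge_tables([tk1], 1))
    return seqs, g


def test_snp_bubble_merges_to_major_allele(rng):
    seqs, g = _snp_fixture(rng)
    assert len(g) == 8  # 4 nodes per strand: flank, two arms, flank
    merged = merge_snp_bubbles(g, 2)
    # single node per strand, spelling the higher-coverage (reference) allele
    assert merged.spellings() == sorted([seqs[0], revcomp(seqs[0])])


def test_three_equal_branches_merge_to_one(rng):
    seqs, g = _snp_fixture(rng, n_alleles=3, ratio=(3, 2, 1))
    merged = merge_snp_bubbles(g, 2)
    assert merged.spellings() == sorted([seqs[0], revcomp(seqs[0])])


def test_unequal_length_branches_survive(rng):
    base = rand_seq(rng, 300)
    alt = base[:150] + rand_seq(rng, 6) + base[150:]  # insertion-like arm
    reads = tile_reads(base, 70, 5) + tile_reads(alt, 70, 5)
    lib = Library.from_sequences("u", reads)
    tk, tk1 = count_library(lib, K)
    g = build_graph(merge_tables([tk], 1), merge_tables([tk1], 1))
    assert len(merge_snp_bubbles(g, 2)) == len(g)


def test_bubble_merge_preserves_component_count(rng):
    _, g = _snp_fixture(rng)
    before = nx.number_weakly_connected_components(g.g)
    merged = merge_snp_bubbles(g, 2)
    assert nx.number_weakly_connected_components(merged.g) == before


def _two_node_graph(rng):
    """Exon-skip style component: E1 branch to two arms reconverging on E3."""
    E1, E2, E3 = rand_seq(rng, 200), rand_seq(rng, 120), rand_seq(rng, 200)
    iso1, iso2 = E1 + E2 + E3, E1 + E3
    g = graph_from_seqs([iso1, iso2], K, read_len=60, step=3)
    return (E1, E2, E3), g


def _brute_force_paired(g: DBGraph, pairs, k: int, c2: int):
    """Independent recount: locate anchors by substring search in node seqs."""
    node_seqs = {n: g.sequence(n) for n in g.g.nodes}

    def locate(window):
        hits = [n for n, s in node_seqs.items() if window in s]
        return hits[0] if len(hits) == 1 else (hits[0] if hits else None)

    counts = {}
    for r1, r2 in pairs:
        cands = []
        for fwd, rev in ((r1, r2), (r2, r1)):
            if len(fwd) < k or len(rev) < k:
                continue
            u = locate(fwd[-k:])
            v = locate(revcomp(rev)[:k])
            if u is not None and v is not None and u != v:
                cands.append((u, v))
        if cands:
            uv = min(cands)
            counts[uv] = counts.get(uv, 0) + 1
    return {uv: n for uv, n in counts.items() if n >= c2}


def test_paired_edges_threshold_and_recount(rng):
    (E1, E2, E3), g = _two_node_graph(rng)
    # 5 pairs spanning E1 -> E3 (rc mate), 1 pair spanning E1 -> E2
    pair_seqs = []
    for _ in range(5):
        pair_seqs += [E1[-60:], revcomp(E3[:60])]
    pair_seqs += [E1[:60], revcomp(E2[:60])]
    lib = Library.from_sequences("p", pair_seqs, paired=True)
    add_paired_edges(g, lib, c2=2)
    assert len(g.paired) == 1
    ((uv, count),) = g.paired.items()
    assert count == 5
    oracle = _brute_force_paired(g, [(pair_seqs[i], pair_seqs[i + 1])
                                     for i in range(0, len(pair_seqs), 2)], K, 2)
    assert g.paired == oracle


def test_pair_with_unanchored_mate_is_skipped(rng):
    _, g = _two_node_graph(rng)
    alien = rand_seq(rng, 60)  # not in the graph
    lib = Library.from_sequences("p", [alien, alien], paired=True)
    counts, failures = count_paired(g, lib)
    assert counts == {}
    assert failures == 1


def test_single_pair_below_cutoff_discarded(rng):
    (E1, E2, E3), g = _two_node_graph(rng)
    lib = Library.from_sequences("p", [E1[-60:], revcomp(E3[:60])], paired=True)
    add_paired_edges(g, lib, c2=2)
    assert g.paired == {}
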