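"""De novo expression: per-node, per-library RPKM by k-mer membership.

A read contributes to a node when it contains at least one of the node's
k-mers (both read orientations are tried; at most one count per node per
read).  RPKM = reads per kilobase of node per million library reads:

    rpkm = read_count * 1e9 / (node_len_nt * library_reads)

computed against the *pre-adjustment* node length, so empty nodes keep a
meaningful coverage value.  The million-reads denominator is the total
number of trimmed reads in the library (empty-after-trim reads included
by default; ``exclude_empty`` switches to non-empty reads only).  A
TPM-like rescaling (values summing to 1e6 per library over nodes) is
offered as a derived measure.
"""

from __future__ import annotations

from typing import IO, Iterable, Union

import numpy as np

from .dbg import DBGraph
from .kmercount import _ENC_LUT, _window_codes
from .readio import Library


def assign_reads(graph: DBGraph, library: Library) -> dict[int, int]:
    """Per-node count of library reads containing >= 1 node k-mer."""
    index = graph.kmer_index()
    k = graph.k
    counts: dict[int, int] = {n: 0 for n in graph.g.nodes}
    sep = np.array([4], dtype=np.uint8)
    for read in library.reads:
        if len(read) < k:
            continue
        a = _ENC_LUT[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
        rc = (np.uint8(3) - a[::-1]) % np.uint8(8)
        codes = _window_codes(np.concatenate([a, sep, rc]), k)
        hit = {index.get(int(c)) for c in codes}
        hit.discard(None)
        for node in hit:
            counts[node] += 1
    return counts


def compute_rpkm(read_count: int, node_len_nt: int, library_reads: int) -> float:
    """reads per kilobase of node per million library reads."""
    if node_len_nt <= 0:
        raise ValueError("node length must be positive (use pre-adjustment length)")
    if library_reads <= 0:
        raise ValueError("library read count must be positive")
    return read_count * 1e9 / (node_len_nt * library_reads)


def attach_expression(
    graph: DBGraph,
    libraries: Iterable[Library],
    exclude_empty: bool = False,
) -> DBGraph:
    """Store per-library read counts and RPKM on every graph node."""
    for node in graph.g.nodes:
        graph.g.nodes[node].setdefault("reads", {})
        graph.g.nodes[node].setdefault("rpkm", {})
    for lib in libraries:
        counts = assign_reads(graph, lib)
        denom = lib.counted_reads(exclude_empty=exclude_empty)
        for node, cnt in counts.items():
            d = graph.g.nodes[node]
            d["reads"][lib.name] = cnt
            d["rpkm"][lib.name] = (
                compute_rpkm(cnt, len(d["seq"]), denom) if denom else 0.0
            )
    return graph


def tpm_from_rpkm(rpkm_by_node: dict[int, float]) -> dict[int, float]:
    """Rescale one library's RPKM values to sum to 1e6 over nodes."""
    total = sum(rpkm_by_node.values())
    if total == 0:
        return {n: 0.0 for n in rpkm_by_node}
    return {n: v * 1e6 / total for n, v in rpkm_by_node.items()}


def write_expression_tsv(
    splicing_graphs, libraries: list[str], stream: Union[str, IO[str]], tpm: bool = True
) -> None:
    """node x library RPKM matrix (plus TPM columns) for the final assembly."""
    own = isinstance(stream, str)
    fh = open(stream, "w") if own else stream
    try:
        cols = [f"rpkm_{lib}" for lib in libraries]
        if tpm:
            cols += [f"tpm_{lib}" for lib in libraries]
        fh.write("node\tlen\t" + "\t".join(cols) + "\n")
        tpms: dict[str, dict[tuple[int, int], float]] = {}
        if tpm:
            for lib in libraries:
                per_node = {
                    (sg.id, n.nid): n.rpkm.get(lib, 0.0)
                    for sg in splicing_graphs
                    for n in sg.nodes
                }
                tpms[lib] = tpm_from_rpkm(per_node)
        for sg in splicing_graphs:
            for n in sg.nodes:
                row = [f"g{sg.id}.n{n.nid}", str(len(n.seq))]
                row += [f"{n.rpkm.get(lib, 0.0):.4f}" for lib in libraries]
                if tpm:
                    row += [f"{tpms[lib][(sg.id, n.nid)]:.4f}" for lib in libraries]
                fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()
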