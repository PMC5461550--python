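"""Two-stage orchestration: parallel per-library counting, sequential assembly.

Stage 1 (:func:`run_count`) enumerates k-mer and (k+1)-mer frequencies for
one library (optionally subdivided into parts of bounded size, counted
independently and merged) and serializes both tables to per-library
archives, plus a JSON manifest entry with checksums.  Independent
invocations over different libraries share no mutable state and may run
concurrently; stored smaller-k tables can seed larger-k runs.

Stage 2 (:func:`run_assemble`) merges the per-library archives under the
coverage cutoff and runs the fixed pipeline order: merge -> build ->
collapse -> tips -> bubbles -> paired edges -> expression -> SCC/tangle
decomposition -> output.  Stage 2 is fully deterministic for a fixed
manifest, so adding one new library only requires stage 1 on that library
followed by a stage-2 rerun.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
import re
import time
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .dbg import AssemblyParams, DBGraph, build_graph, merge_tables
from .express import attach_expression, write_expression_tsv
from .kmercount import FrequencyTable, count_library, load_table, save_table
from .readio import Library, write_assembly
from .simplify import add_paired_edges, merge_snp_bubbles, remove_tips
from .splice import (
    SplicingGraph,
    extract_splicing_graphs,
    junction_contexts,
    junction_signatures,
)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _split_library(lib: Library, split_bases: int) -> list[Library]:
    parts: list[Library] = []
    cur: list = []
    cur_bases = 0
    for read in lib.reads:
        cur.append(read)
        cur_bases += len(read)
        if cur_bases >= split_bases:
            parts.append(Library(f"{lib.name}", cur, lib.paired))
            cur, cur_bases = [], 0
    if cur or not parts:
        parts.append(Library(f"{lib.name}", cur, lib.paired))
    return parts


def _archive_path(out_dir: str, name: str, k_len: int) -> str:
    return os.path.join(out_dir, f"{name}.k{k_len}.skt")


def _find_reusable(out_dir: str, name: str, k: int) -> Optional[str]:
    best: tuple[int, str] | None = None
    for path in glob.glob(os.path.join(out_dir, f"{name}.k*.skt")):
        m = re.search(r"\.k(\d+)\.skt$", path)
        if m and int(m.group(1)) <= k:
            if best is None or int(m.group(1)) > best[0]:
                best = (int(m.group(1)), path)
    return best[1] if best else None


def run_count(
    name: str,
    fastq1: str,
    fastq2: Optional[str] = None,
    interleaved: bool = False,
    k: int = 25,
    k0: int = 12,
    qmin: int = 15,
    out_dir: str = ".",
    split_bases: Optional[int] = None,
    reuse: bool = False,
    force: bool = False,
) -> dict:
    """Stage 1 for one library; returns the manifest entry written to disk."""
    os.makedirs(out_dir, exist_ok=True)
    path_k = _archive_path(out_dir, name, k)
    path_k1 = _archive_path(out_dir, name, k + 1)
    meta_path = os.path.join(out_dir, f"{name}.json")
    if os.path.exists(meta_path) and not force:
        old = json.load(open(meta_path))
        if old.get("k") != k:
            raise FileExistsError(
                f"{meta_path} exists with k={old.get('k')} != {k}; "
                "use force=True to overwrite"
            )
        if os.path.exists(path_k) and os.path.exists(path_k1):
            raise FileExistsError(
                f"archives for {name!r} at k={k} already exist; use force=True"
            )

    lib = Library.from_fastq(name, fastq1, fastq2, interleaved=interleaved, qmin=qmin)
    start = None
    if reuse:
        reusable = _find_reusable(out_dir, name, k)
        if reusable:
            start = load_table(reusable)
    if split_bases and start is None:
        parts = _split_library(lib, split_bases)
        part_tables = [count_library(p, k, k0) for p in parts]
        tab_k = merge_tables([t for t, _ in part_tables], c=1)
        tab_k1 = merge_tables([t for _, t in part_tables], c=1)
        tab_k.library = name
        tab_k1.library = name
    else:
        tab_k, tab_k1 = count_library(lib, k, k0, start_table=start)
    save_table(tab_k, path_k)
    save_table(tab_k1, path_k1)
    entry = {
        "name": name,
        "fastq": [p for p in (fastq1, fastq2) if p],
        "interleaved": interleaved,
        "paired": lib.paired,
        "qmin": qmin,
        "k": k,
        "k0": k0,
        "total_reads": lib.total_reads,
        "total_bases": lib.total_bases,
        "archives": {
            str(k): {"path": path_k, "sha256": _sha256(path_k)},
            str(k + 1): {"path": path_k1, "sha256": _sha256(path_k1)},
        },
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(meta_path, "w") as fh:
        json.dump(entry, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return entry


@dataclass
class AssemblyResult:
    graphs: list[SplicingGraph]
    dbgraph: DBGraph
    libraries: list[Library]
    log: list[str] = field(default_factory=list)

    def log_text(self) -> str:
        return "".join(line + "\n" for line in self.log)


def assemble_libraries(
    libraries: list[Library],
    params: AssemblyParams,
    tables: Optional[list[tuple[FrequencyTable, FrequencyTable]]] = None,
) -> AssemblyResult:
    """The sequential stage on in-memory libraries (stage 1 run inline
    unless per-library (k, k+1) tables are supplied)."""
    if not libraries:
        raise ValueError("no libraries")
    log: list[str] = []
    if tables is None:
        tables = [count_library(lib, params.k, params.k0) for lib in libraries]
    for lib, (tk, _) in zip(libraries, tables):
        log.append(f"count\t{lib.name}\tkmers\t{len(tk)}")
    merged_k = merge_tables([tk for tk, _ in tables], params.c)
    merged_e = merge_tables([te for _, te in tables], params.c)
    log.append(f"merge\tkmers\t{len(merged_k)}")
    log.append(f"merge\tedges\t{len(merged_e)}")

    graph = build_graph(merged_k, merged_e)
    log.append(f"build\tnodes\t{len(graph)}")
    log.append(f"build\tedges\t{graph.g.number_of_edges()}")

    graph = remove_tips(graph, params.effective_tip_len)
    log.append(f"tips\tnodes\t{len(graph)}")

    graph = merge_snp_bubbles(graph, params.bubble_max_mismatch)
    log.append(f"bubbles\tnodes\t{len(graph)}")

    total_bases = sum(lib.total_bases for lib in libraries)
    paired_libs = [lib for lib in libraries if lib.paired]
    if paired_libs:
        c2 = params.effective_c2(total_bases)
        add_paired_edges(graph, paired_libs, c2)
        log.append(f"paired\tc2\t{c2}")
        log.append(f"paired\tedges\t{len(graph.paired)}")
        log.append(
            f"paired\tanchor_failures\t{getattr(graph, 'paired_anchor_failures', 0)}"
        )

    attach_expression(graph, libraries, exclude_empty=params.rpkm_exclude_empty)
    graphs = extract_splicing_graphs(graph, params)
    log.append(f"extract\tsplicing_graphs\t{len(graphs)}")
    log.append(f"extract\tnodes\t{sum(len(sg.nodes) for sg in graphs)}")
    return AssemblyResult(graphs, graph, libraries, log)


def load_manifest(archive_dir: str, k: int, verify: bool = True) -> list[dict]:
    """Collect stage-1 manifest entries; refuse mismatched or missing archives."""
    entries = []
    for meta_path in sorted(glob.glob(os.path.join(archive_dir, "*.json"))):
        entry = json.load(open(meta_path))
        if not isinstance(entry, dict) or "archives" not in entry:
            continue
        if entry.get("k") != k:
            raise ValueError(
                f"{meta_path}: archive was produced with k={entry.get('k')}, "
                f"assembly requested k={k}"
            )
        for k_len in (k, k + 1):
            info = entry["archives"][str(k_len)]
            if not os.path.exists(info["path"]):
                raise FileNotFoundError(f"missing stage-1 archive {info['path']}")
            if verify and _sha256(info["path"]) != info["sha256"]:
                raise ValueError(f"checksum mismatch for {info['path']}")
        entries.append(entry)
    if not entries:
        raise ValueError("no libraries")
    return entries


def run_assemble(
    archive_dir: str,
    params: AssemblyParams,
    out_prefix: str,
    verify: bool = True,
) -> AssemblyResult:
    """Stage 2 from stored archives; writes FASTA, RPKM TSV, junction TSV, log."""
    entries = load_manifest(archive_dir, params.k, verify=verify)
    tables = []
    libraries = []
    for entry in entries:
        tab_k = load_table(entry["archives"][str(params.k)]["path"])
        tab_k1 = load_table(entry["archives"][str(params.k + 1)]["path"])
        tables.append((tab_k, tab_k1))
        fq = entry["fastq"]
        libraries.append(
            Library.from_fastq(
                entry["name"],
                fq[0],
                fq[1] if len(fq) > 1 else None,
                interleaved=entry.get("interleaved", False),
                qmin=entry.get("qmin", 15),
            )
        )
    result = assemble_libraries(libraries, params, tables=tables)

    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    write_assembly(result.graphs, out_prefix + ".fasta")
    write_expression_tsv(
        result.graphs, sorted(lib.name for lib in libraries), out_prefix + ".rpkm.tsv"
    )
    with open(out_prefix + ".junctions.tsv", "w") as fh:
        fh.write("graph\tsource\ttarget\tsignature\tboundary\tcontext\n")
        for sg in result.graphs:
            ctxs = {e: (ctx, b) for e, ctx, b in junction_contexts(sg)}
            for j in junction_signatures(sg):
                sig = j.signature if j.signature else "-"
                ctx, b = ctxs[j.edge]
                fh.write(
                    f"g{sg.id}\tn{j.edge[0]}\tn{j.edge[1]}\t{sig}\t{b}\t{ctx}\n"
                )
    with open(out_prefix + ".log", "w") as fh:
        fh.write(result.log_text())
    return result
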