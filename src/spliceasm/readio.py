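"""FASTQ input, quality trimming, and annotated-FASTA assembly output.

Reads enter the assembler as plain or gzip-compressed FASTQ (single-end,
two synchronized paired files, or one interleaved file).  Each read is
trimmed at the first base whose phred quality drops below a threshold
(default 15): everything from that base onward is discarded.  The final
assembly is written as "annotated FASTA", one entry per splicing-graph
node, with the graph topology and per-library RPKM values embedded in the
header line:

    >g<GID>.n<NID> len=<int> out=<NID,...|-> pair=<NID:count,...|-> rpkm=<LIB:float;...>

Empty nodes (sequence fully consumed by junction adjustment) are emitted
with ``len=0`` and an empty sequence line; they encode isoforms that skip
a segment.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_QMIN = 15

_MATE_SUFFIX = re.compile(r"/[12]$")


@dataclass
class ReadRecord:
    """A single (possibly trimmed) sequencing read."""

    id: str
    sequence: str
    qualities: list[int]
    mate: Optional[int] = None  # 1 or 2 for paired data
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"record {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path: str, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _pair_key(title: str) -> str:
    name = title.split()[0] if title.split() else title
    return _MATE_SUFFIX.sub("", name)


def _records_from(handle: IO[str], mate: Optional[int]) -> Iterator[ReadRecord]:
    last = "<start of file>"
    it = FastqGeneralIterator(handle)
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record after {last!r}: {exc}") from exc
        last = title
        name = title.split()[0] if title.split() else title
        quals = [ord(ch) - 33 for ch in qual]
        yield ReadRecord(
            id=name,
            sequence=seq.upper(),
            qualities=quals,
            mate=mate,
            pair_id=_pair_key(title) if mate else None,
        )


def parse_fastq(
    stream: Union[str, IO[str]],
    paired_stream: Union[str, IO[str], None] = None,
    interleaved: bool = False,
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from FASTQ input, in input order.

    ``paired_stream`` gives the synchronized mate-2 file; ``interleaved``
    marks a single file with alternating mates.  Mate tags (1/2) are set
    from the stream of origin.  Gzip-compressed paths are decompressed
    transparently.  Malformed records abort with the offending record id.
    """
    h1 = _open_maybe_gzip(stream) if isinstance(stream, str) else stream
    if paired_stream is not None:
        h2 = (
            _open_maybe_gzip(paired_stream)
            if isinstance(paired_stream, str)
            else paired_stream
        )
        it1 = _records_from(h1, mate=1)
        it2 = _records_from(h2, mate=2)
        for r1 in it1:
            try:
                r2 = next(it2)
            except StopIteration:
                raise ValueError(f"paired file truncated: no mate for {r1.id!r}")
            r2.pair_id = r1.pair_id  # synchronized order defines pairing
            yield r1
            yield r2
        if next(it2, None) is not None:
            raise ValueError("paired file truncated: extra mate-2 records")
    elif interleaved:
        mate = 1
        for rec in _records_from(h1, mate=None):
            rec.mate = mate
            rec.pair_id = _pair_key(rec.id)
            yield rec
            mate = 2 if mate == 1 else 1
    else:
        yield from _records_from(h1, mate=None)


def trim_read(record: ReadRecord, qmin: int = DEFAULT_QMIN) -> ReadRecord:
    """Keep the prefix strictly before the first base with quality < qmin.

    A read whose first base fails becomes empty; it contributes no k-mers
    downstream but still counts as a sequenced read of its library.
    """
    cut = len(record.qualities)
    for i, q in enumerate(record.qualities):
        if q < qmin:
            cut = i
            break
    if cut == len(record.sequence):
        return record
    return ReadRecord(
        id=record.id,
        sequence=record.sequence[:cut],
        qualities=record.qualities[:cut],
        mate=record.mate,
        pair_id=record.pair_id,
    )


@dataclass
class Library:
    """One RNA-Seq library: a named collection of trimmed reads.

    ``total_reads`` counts all sequenced reads, including reads that became
    empty after trimming — the RPKM denominator is per million *reads* of
    the library.  Callers that prefer to exclude empty reads can use
    :meth:`counted_reads`.
    """

    name: str
    reads: list[ReadRecord] = field(default_factory=list)
    paired: bool = False

    @property
    def total_reads(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def counted_reads(self, exclude_empty: bool = False) -> int:
        if exclude_empty:
            return sum(1 for r in self.reads if len(r) > 0)
        return self.total_reads

    def sequences(self) -> Iterator[str]:
        for r in self.reads:
            yield r.sequence

    def pairs(self) -> list[tuple[ReadRecord, ReadRecord]]:
        """Mate pairs (mate1, mate2); reads missing a partner are skipped."""
        out: list[tuple[ReadRecord, ReadRecord]] = []
        pending: dict[str, ReadRecord] = {}
        for r in self.reads:
            if r.mate not in (1, 2):
                continue
            key = r.pair_id or r.id
            other = pending.pop(key, None)
            if other is None:
                pending[key] = r
            elif other.mate != r.mate:
                out.append((other, r) if other.mate == 1 else (r, other))
        self.n_unpaired = len(pending)
        return out

    @classmethod
    def from_fastq(
        cls,
        name: str,
        path1: str,
        path2: Optional[str] = None,
        interleaved: bool = False,
        qmin: int = DEFAULT_QMIN,
        keep_empty: bool = True,
    ) -> "Library":
        reads = []
        for rec in parse_fastq(path1, path2, interleaved=interleaved):
            trimmed = trim_read(rec, qmin)
            if keep_empty or len(trimmed) > 0:
                reads.append(trimmed)
        return cls(name=name, reads=reads, paired=path2 is not None or interleaved)

    @classmethod
    def from_sequences(
        cls,
        name: str,
        seqs: Iterable[str],
        paired: bool = False,
        qual: int = 40,
    ) -> "Library":
        """Build an in-memory library from raw sequences (testing/simulation).

        With ``paired=True`` the sequences are taken as alternating
        mate1/mate2 reads of successive pairs.
        """
        reads = []
        for i, s in enumerate(seqs):
            mate = (i % 2) + 1 if paired else None
            pid = f"{name}.p{i // 2}" if paired else None
            reads.append(
                ReadRecord(
                    id=f"{name}.r{i}",
                    sequence=s,
                    qualities=[qual] * len(s),
                    mate=mate,
                    pair_id=pid,
                )
            )
        return cls(name=name, reads=reads, paired=paired)


# ---------------------------------------------------------------------------
# annotated FASTA


def _fmt_rpkm(rpkm: dict[str, float]) -> str:
    return ";".join(f"{lib}:{rpkm[lib]:.4f}" for lib in sorted(rpkm))


def write_assembly(splicing_graphs, stream: Union[str, IO[str]]) -> None:
    """Write splicing graphs as annotated FASTA, one entry per node."""
    own = isinstance(stream, str)
    fh = open(stream, "w") if own else stream
    try:
        for sg in splicing_graphs:
            ids = {n.nid for n in sg.nodes}
            for nid, tgt in sg.edges:
                if tgt not in ids or nid not in ids:
                    raise ValueError(
                        f"graph g{sg.id}: edge {nid}->{tgt} references missing node"
                    )
            for node in sg.nodes:
                outs = sorted(t for (s, t) in sg.edges if s == node.nid)
                prs = sorted(
                    (t, c) for (s, t), c in sg.paired.items() if s == node.nid
                )
                out_s = ",".join(f"n{t}" for t in outs) if outs else "-"
                pair_s = ",".join(f"n{t}:{c}" for t, c in prs) if prs else "-"
                rpkm_s = _fmt_rpkm(node.rpkm) if node.rpkm else "-"
                fh.write(
                    f">g{sg.id}.n{node.nid} len={len(node.seq)} "
                    f"out={out_s} pair={pair_s} rpkm={rpkm_s}\n"
                )
                fh.write(node.seq + "\n")
    finally:
        if own:
            fh.close()


@dataclass
class ParsedGraph:
    """Topology and expression read back from annotated FASTA."""

    id: int
    nodes: dict[int, str] = field(default_factory=dict)  # nid -> sequence
    rpkm: dict[int, dict[str, float]] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    paired: dict[tuple[int, int], int] = field(default_factory=dict)


_HEADER = re.compile(
    r"^>g(\d+)\.n(\d+) len=(\d+) out=(\S+) pair=(\S+) rpkm=(\S+)$"
)


def parse_assembly(stream: Union[str, IO[str]]) -> list[ParsedGraph]:
    """Read the annotated-FASTA dialect back (round-trip counterpart)."""
    own = isinstance(stream, str)
    fh = open(stream) if own else stream
    graphs: dict[int, ParsedGraph] = {}
    try:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                m = _HEADER.match(line)
                if not m:
                    raise ValueError(f"unparsable header: {line!r}")
                header = m
                continue
            if header is None:
                raise ValueError("sequence line before any header")
            gid, nid = int(header.group(1)), int(header.group(2))
            g = graphs.setdefault(gid, ParsedGraph(id=gid))
            if len(line) != int(header.group(3)):
                raise ValueError(f"g{gid}.n{nid}: len field does not match sequence")
            g.nodes[nid] = line
            if header.group(4) != "-":
                for tok in header.group(4).split(","):
                    g.edges.add((nid, int(tok.lstrip("n"))))
            if header.group(5) != "-":
                for tok in header.group(5).split(","):
                    t, c = tok.split(":")
                    g.paired[(nid, int(t.lstrip("n")))] = int(c)
            if header.group(6) != "-":
                g.rpkm[nid] = {
                    lib: float(v)
                    for lib, v in (tok.split(":") for tok in header.group(6).split(";"))
                }
            header = None
    finally:
        if own:
            fh.close()
    return [graphs[g] for g in sorted(graphs)]
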