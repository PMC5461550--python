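"""Synthetic transcriptome and RNA-Seq read generator with ground truth.

The generator emulates the structures the assembler is built to recover:
genes made of exons with long shared flanking exons, optional skipped
internal exons (two isoforms sharing their outer exons), biallelic SNP
bubbles, per-library lognormal expression, and error-bearing non-strand-
specific paired-end reads.  Truth tables record alternative-splicing
junction windows (the 2k nucleotides around each variable exon boundary)
and per-transcript read counts, so junction sensitivity/specificity and
RPKM recovery can be scored without any reference database.

Fragment start positions include transcript-terminal fragments (as
physical shearing produces): a fragment whose nominal start lies before
position 0 or whose nominal end runs past the transcript end is clipped,
which keeps coverage near-uniform out to the transcript ends instead of
tapering over an insert length.  The error model is substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Union

import numpy as np

from .kmercount import revcomp
from .readio import Library, ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """Parameters of the synthetic transcriptome / read generator."""

    n_genes: int = 20
    exons_min: int = 2
    exons_max: int = 4
    exon_len_min: int = 150
    exon_len_max: int = 400
    flank_exon_min: int = 120  # first/last exon floor; keep >= 2k so bubbles resolve
    skip_prob: float = 0.3
    snp_prob: float = 0.1
    allele_ratio: float = 0.5
    expr_mu: float = 1.0
    expr_sigma: float = 0.8
    n_libraries: int = 2
    read_len: int = 100
    insert_mean: int = 250
    insert_sd: int = 30
    error_rate: float = 0.005
    phred: int = 35
    coverage: float = 30.0
    k_context: int = 25  # junction window half-width
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.skip_prob, self.snp_prob, self.allele_ratio):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.exon_len_min, self.flank_exon_min, self.read_len) < 1:
            raise ValueError("lengths must be >= 1")
        if self.flank_exon_min < 2 * self.k_context:
            raise ValueError(
                "flanking exons must be at least 2k so junction windows fit"
            )


@dataclass
class Transcript:
    id: str
    gene: str
    sequence: str
    exon_ids: tuple[int, ...]
    boundaries: tuple[int, ...]  # positions of exon-exon boundaries in sequence


@dataclass
class Truth:
    """Ground truth of one simulated dataset."""

    transcripts: list[Transcript]
    junctions: dict[str, list[str]]  # gene -> 2k windows at variable boundaries
    abundance: dict[str, dict[str, float]]  # lib -> transcript id -> weight
    read_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def all_junction_windows(self) -> list[str]:
        return sorted({w for ws in self.junctions.values() for w in ws})


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_transcriptome(
    spec: SimSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[Transcript], Truth]:
    """Genes with optional skip isoforms and SNP alleles, plus truth tables.

    Junction truth lists, per gene, the 2k windows around exon adjacencies
    that are *not* shared by all of the gene's isoforms (adjacencies
    common to every isoform never branch the graph).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    k = spec.k_context
    transcripts: list[Transcript] = []
    junctions: dict[str, list[str]] = {}
    for gi in range(spec.n_genes):
        gene = f"gene{gi:03d}"
        n_ex = int(rng.integers(spec.exons_min, spec.exons_max + 1))
        exons = []
        for ei in range(n_ex):
            lo = spec.flank_exon_min if ei in (0, n_ex - 1) else spec.exon_len_min
            hi = max(spec.exon_len_max, lo)
            exons.append(_random_seq(rng, int(rng.integers(lo, hi + 1))))
        isoform_structures = [tuple(range(n_ex))]
        if n_ex >= 3 and rng.random() < spec.skip_prob:
            skip = int(rng.integers(1, n_ex - 1))
            isoform_structures.append(tuple(i for i in range(n_ex) if i != skip))
        shared = set(zip(isoform_structures[0], isoform_structures[0][1:]))
        for s in isoform_structures[1:]:
            shared &= set(zip(s, s[1:]))

        snp = rng.random() < spec.snp_prob
        gene_tx: list[Transcript] = []
        gene_junctions: list[str] = []
        for ii, structure in enumerate(isoform_structures):
            seq_parts = [exons[e] for e in structure]
            seq = "".join(seq_parts)
            bounds = tuple(np.cumsum([len(p) for p in seq_parts])[:-1].tolist())
            tx = Transcript(
                id=f"{gene}.iso{ii}", gene=gene, sequence=seq,
                exon_ids=structure, boundaries=bounds,
            )
            gene_tx.append(tx)
            for adj, b in zip(zip(structure, structure[1:]), bounds):
                if adj not in shared and len(isoform_structures) > 1:
                    gene_junctions.append(seq[b - k : b + k])
        if snp:
            # biallelic substitution inside an internal position of the
            # full isoform, away from exon boundaries by >= k
            base_tx = gene_tx[0]
            lo, hi = k + 1, len(base_tx.sequence) - k - 1
            forbidden = set()
            for b in base_tx.boundaries:
                forbidden.update(range(b - k, b + k + 1))
            for _ in range(50):
                pos = int(rng.integers(lo, hi))
                if pos not in forbidden:
                    break
            old = base_tx.sequence[pos]
            new = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
            alt = base_tx.sequence[:pos] + new + base_tx.sequence[pos + 1 :]
            gene_tx.append(
                replace(base_tx, id=f"{base_tx.id}.alt", sequence=alt)
            )
        transcripts.extend(gene_tx)
        junctions[gene] = sorted(set(gene_junctions))

    abundance: dict[str, dict[str, float]] = {}
    for li in range(spec.n_libraries):
        lib = f"lib{li}"
        weights = {}
        for tx in transcripts:
            w = float(rng.lognormal(spec.expr_mu, spec.expr_sigma))
            if tx.id.endswith(".alt"):
                # alleles split the gene's expression by the allele ratio
                base = weights[tx.id[: -len(".alt")]]
                weights[tx.id[: -len(".alt")]] = base * spec.allele_ratio
                w = base * (1.0 - spec.allele_ratio)
            weights[tx.id] = w
        abundance[lib] = weights
    return transcripts, Truth(transcripts, junctions, abundance)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    a = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(a.size) < rate
    if not mask.any():
        return seq
    idx = np.nonzero(mask)[0]
    cur = np.searchsorted(_BASES, a[idx])  # A,C,G,T ascii are sorted
    shift = rng.integers(1, 4, size=idx.size)
    a[idx] = _BASES[(cur + shift) % 4]
    return a.tobytes().decode()


def simulate_reads(
    transcripts: list[Transcript],
    spec: SimSpec,
    rng: Optional[np.random.Generator] = None,
    abundance: Optional[dict[str, dict[str, float]]] = None,
    truth: Optional[Truth] = None,
) -> list[Library]:
    """Paired-end libraries sampled from the transcripts.

    Reads are sampled at per-library abundances with uniform fragment
    placement (terminal fragments included), strand chosen uniformly, and
    substitution errors at the configured rate.  Identical rng state gives
    byte-identical output.  Transcripts shorter than the read length are
    skipped with a warning attribute on the returned library.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    if abundance is None:
        abundance = truth.abundance if truth is not None else None
    rl = spec.read_len
    usable = [t for t in transcripts if len(t.sequence) >= rl]
    skipped = [t.id for t in transcripts if len(t.sequence) < rl]
    total_nt = sum(len(t.sequence) for t in usable)
    libs: list[Library] = []
    for li in range(spec.n_libraries):
        name = f"lib{li}"
        if not usable:
            lib = Library(name=name, reads=[], paired=True)
            lib.skipped_transcripts = skipped
            libs.append(lib)
            if truth is not None:
                truth.read_counts[name] = {}
            continue
        if abundance is not None:
            ab = abundance[name]
            w = np.array([ab.get(t.id, 1.0) * len(t.sequence) for t in usable])
        else:
            w = np.array([float(len(t.sequence)) for t in usable])
        w = w / w.sum()
        n_pairs = max(1, int(round(spec.coverage * total_nt / (2 * rl))))
        per_tx = rng.multinomial(n_pairs, w)
        reads: list[ReadRecord] = []
        counts: dict[str, int] = {}
        for t, n in zip(usable, per_tx):
            counts[t.id] = int(n)
            if n == 0:
                continue
            L = len(t.sequence)
            frags = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=n)).astype(int)
            frags = np.clip(frags, rl, max(rl, L))
            lo = -(frags - rl)
            hi = L - rl  # inclusive
            starts = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
            flips = rng.random(n) < 0.5
            for j in range(int(n)):
                s = max(0, int(starts[j]))
                e = min(L, int(starts[j]) + int(frags[j]))
                frag = t.sequence[s:e]
                r1 = _apply_errors(frag[:rl], spec.error_rate, rng)
                r2 = _apply_errors(revcomp(frag[-rl:]), spec.error_rate, rng)
                if flips[j]:
                    r1, r2 = r2, r1
                pid = f"{name}.{t.id}.{j}"
                quals = [spec.phred] * rl
                reads.append(ReadRecord(f"{pid}/1", r1, list(quals), mate=1, pair_id=pid))
                reads.append(ReadRecord(f"{pid}/2", r2, list(quals), mate=2, pair_id=pid))
        lib = Library(name=name, reads=reads, paired=True)
        lib.skipped_transcripts = skipped
        libs.append(lib)
        if truth is not None:
            truth.read_counts[name] = counts
    return libs


# ---------------------------------------------------------------------------
# file output


def write_fasta(transcripts: list[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id} gene={t.gene}\n{t.sequence}\n")


def write_fastq_pair(library: Library, path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rec in library.reads:
            fh = f1 if rec.mate == 1 else f2
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def write_truth(truth: Truth, junctions_path: str, expression_path: str) -> None:
    with open(junctions_path, "w") as fh:
        fh.write("gene\twindow\n")
        for gene in sorted(truth.junctions):
            for w in truth.junctions[gene]:
                fh.write(f"{gene}\t{w}\n")
    with open(expression_path, "w") as fh:
        fh.write("transcript\tgene\tlength\tlibrary\tweight\treads\n")
        for lib in sorted(truth.abundance):
            for t in truth.transcripts:
                w = truth.abundance[lib].get(t.id, 0.0)
                n = truth.read_counts.get(lib, {}).get(t.id, 0)
                fh.write(
                    f"{t.id}\t{t.gene}\t{len(t.sequence)}\t{lib}\t{w:.6f}\t{n}\n"
                )


def simulate_dataset(spec: SimSpec, out_dir: str) -> tuple[list[Transcript], Truth, list[Library]]:
    """Simulate and write a complete dataset under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    transcripts, truth = simulate_transcriptome(spec, rng)
    libs = simulate_reads(transcripts, spec, rng, truth=truth)
    write_fasta(transcripts, os.path.join(out_dir, "transcripts.fasta"))
    for lib in libs:
        write_fastq_pair(
            lib,
            os.path.join(out_dir, f"{lib.name}_1.fastq"),
            os.path.join(out_dir, f"{lib.name}_2.fastq"),
        )
    write_truth(
        truth,
        os.path.join(out_dir, "truth_junctions.tsv"),
        os.path.join(out_dir, "truth_expression.tsv"),
    )
    return transcripts, truth, libs
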