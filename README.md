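# spliceasm

Memory-bounded de novo transcriptome assembly of multi-library RNA-Seq
into per-gene **splicing graphs** with de novo **RPKM** expression
estimates.

## The problem and the approach

Assembling a transcriptome without a reference genome from many RNA-Seq
libraries (different conditions, stages, labs) is limited by memory: the
usual hash-based k-mer indexes of transcriptome assemblers do not fit on
moderate machines once the data reach hundreds of gigabases.  spliceasm
splits the work into two stages:

1. **Parallel stage** — each library (or part of a library) is processed
   independently.  k-mer frequencies are enumerated *iteratively*: starting
   from a moderate mer length k0 (default 12), the sorted table of k'-mers
   is extended one base at a time.  For each table of n entries an array of
   4n slots (one per possible next nucleotide) is filled in a single pass
   over the reads by binary-searching each (k'+1)-mer's prefix; zero slots
   are pruned.  The memory per mer is a small constant (codes are 2 bits
   per base in a ≤128-bit integer), tables for a smaller k seed runs at a
   larger k, and both the k-mer table (graph vertices) and the (k+1)-mer
   table (edge support) are archived per library.

2. **Sequential stage** — the per-library tables are merge-sorted, counts
   summed, and a k-mer coverage cutoff *c* is applied **before** graph
   construction, keeping the de Bruijn graph small.  Maximal nonbranching
   paths collapse into sequence nodes.  The graph is then cleaned: dead-end
   *tips* shorter than 2k are removed iteratively; equal-length
   *split-then-merge* bubbles with few mismatches (SNPs, recurrent errors)
   merge into their highest-coverage branch; *paired edges* u→v are counted
   from mate pairs (node of the forward mate's last k-mer → node of the
   reverse mate's first k-mer) and kept above a cutoff c2.  Cyclic strongly
   connected components and forward–backward tangles (components containing
   a node and its reverse complement — an artifact of non-strand-specific
   data) are broken into single-node graphs; every remaining weakly
   connected component is an acyclic **splicing graph**: nodes ≈ exonic
   segments, edges ≈ splice junctions, one graph ≈ one gene's isoform
   family.  Junction adjustment removes each k−1 de Bruijn overlap exactly
   once (empty nodes encode exon-skipping isoforms), one orientation per
   graph is kept, and graphs with longest path < 100 nt are dropped.

Expression is estimated de novo, per node and per library:

```
RPKM = reads_containing_a_node_kmer × 10^9 / (node_length_nt × library_reads)
```

computed against pre-adjustment node lengths so branch coverage is
preserved.  A TPM-like rescaling is also written.

Because stage 1 is per-library, adding a new library later only requires
counting that library and re-running stage 2 — the result is byte-identical
to a from-scratch run on all libraries.

## Worked example

Simulate a small ground-truth dataset (5 genes, two of them with an
exon-skipping isoform, two paired-end libraries), assemble it, and score
the recovered splice junctions:

```bash
spliceasm simulate -o data --n-genes 5 --coverage 30 --seed 6
spliceasm count data/lib0_1.fastq data/lib0_2.fastq --name lib0 -k 25 -o arch
spliceasm count data/lib1_1.fastq data/lib1_2.fastq --name lib1 -k 25 -o arch
spliceasm assemble arch -o asm -k 25 -c 3
spliceasm eval --junctions asm.junctions.tsv --truth-junctions data/truth_junctions.tsv
```

which prints (among the per-stage tallies):

```
merge	kmers	7756
build	nodes	36
tips	nodes	28
bubbles	nodes	22
paired	edges	10
extract	splicing_graphs	5
extract	nodes	11
{"sensitivity": 1.0, "specificity": 1.0}
```

Five splicing graphs are recovered, one per simulated gene; the
skip-isoform genes contribute the branch nodes (11 nodes over 5 graphs).
All annotated junction windows are found in the assembly and every
assembled junction corresponds to an annotated one.  The assembly itself
is annotated FASTA, one entry per node, with topology and per-library
RPKM embedded in the header:

```
>g1.n1 len=673 out=- pair=- rpkm=lib0:126893.6836;lib1:206713.9039
CACTTAGGTCGAATTGCCTGCGCTTCATCGCGTACAACACC...
```

(RPKM values are large here because the toy libraries hold only ~1,500
reads; the denominator is per million reads.)  `asm.rpkm.tsv` carries the
node × library RPKM/TPM matrix, and `asm.junctions.tsv` the 2k-length
junction signatures.

The same pipeline is available as a Python API (`spliceasm.SimSpec`,
`assemble_libraries`, `score_junctions`, ...); see `docs/methods.md` for
the model, parameters and design choices.

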