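# Methods

## Model

spliceasm assembles non-strand-specific RNA-Seq into splicing graphs: one
acyclic directed graph per gene, whose nodes are exonic sequence segments
and whose edges are splice junctions.  It deliberately does *not*
enumerate transcript sets — a splicing graph represents the isoform
family compactly and postpones isoform-level inference to downstream
analysis.  The pipeline assumes substitution-dominated sequencing error,
reads from both strands in unknown orientation, and expression varying
freely across libraries.

### Stage 1: iterative k-mer enumeration

Mers are coded 2 bits/base (A=0 … T=3, most significant first), so
integer order equals lexicographic order; mer length is capped at 63 (a
128-bit code).  Counting starts at k0 (default 12, chosen so the initial
enumeration is cheap but the table is already much smaller than 4^k0) and
extends one base per iteration: a 4n-slot array indexed by (prefix
position × final base) is filled in one pass over the reads with binary
search on the prefix, then pruned.  Both read orientations are scanned
and both oriented mers are stored, with no canonicalization, because the
downstream graph explicitly carries forward and backward nodes and the
tangle decomposition expects them.  Mers containing N are skipped — a
consequence of the 2-bit alphabet.  Mer lengths ≤ 32 run through a
vectorized uint64 path; longer mers use arbitrary-precision integers with
identical semantics (the tests assert equality of both paths against a
dictionary-count oracle).

Archives store the sorted table verbatim (16-byte little-endian code,
32-bit count) so stage 2 can merge libraries by streaming.  A library may
be subdivided into parts of bounded size, counted independently and
merged by count addition — the result is identical to counting the whole
library, which the tests check byte-for-byte.

### Stage 2: graph construction and cleaning

Per-library tables are multi-way merged with counts summed; a k-mer (and
likewise a (k+1)-mer, which supports an edge) enters the graph only if
its summed count is ≥ c.  Applying the cutoff *before* building the
graph, rather than pruning low-support paths afterwards, is what bounds
the memory of the sequential stage.  The cutoff is read as "keep iff
count ≥ c", and the same c is used for vertices and edges so that edge
support can never exceed vertex support.

Cleaning order: tips → bubbles → paired edges.

* **Tips** — nodes with exactly one dead side (in-degree 0 xor out-degree
  0) and spelled length < 2k are removed, the graph is re-collapsed, and
  the sweep repeats to a fixpoint.  Whole isolated nodes are not tips.
  The threshold 2k is the shortest length at which a dead end can carry a
  k-mer not explained by a single erroneous base at a branch.
* **SNP bubbles** — where *all* out-branches of a node run through simple
  one-in/one-out nodes reconverging on one node, with equal branch
  lengths and ≤ 2 mismatches per branch pair (flag-tunable; "very few"
  quantified as 2), the branches merge into the one with the highest
  k-mer coverage.  Coverage ties break on the orientation-canonical
  sequence so a graph and its mirror simplify symmetrically.  Branches of
  different lengths are left alone: they are candidate alternative
  splicing, exactly what the assembler must preserve.
* **Paired edges** — for each mate pair, the node holding the last k-mer
  of the forward mate and the node holding the first k-mer of the
  reverse-complemented reverse mate define u→v.  Orientation is unknown,
  so both mutual orientations are tried; because the graph stores both
  strands, both usually resolve, and the tie goes to the
  lexicographically smaller (u, v) so counting is deterministic.  Pairs
  anchoring to a single node (u = v) are not counted.  Edges with count
  ≥ c2 are kept.  c2 defaults to max(2, 20 × total_gigabases), an
  explicit, flag-tunable reading of "proportional to dataset size".

### Decomposition into splicing graphs

Cyclic SCCs (repeats) and weak components containing a node together
with its reverse complement (forward–backward tangles, including
palindromic nodes) lose their junction information: each member node is
emitted as a singleton splicing graph.  The remaining weak components
are provably acyclic and become one splicing graph each.  Exactly one
orientation survives per graph: the one whose sorted node-sequence tuple
is lexicographically smaller than its reverse complement's (singletons
use the same rule on their single sequence).  Node and graph ids derive
from the smallest constituent k-mer code, making repeated runs
byte-identical.  Graphs whose longest path (dynamic program over the
topological order, summing adjusted node lengths) is < 100 nt are
dropped; tangle singletons obey the same filter.

### Junction adjustment

Consecutive de Bruijn nodes share k−1 characters.  Adjustment removes
each overlap exactly once so every spelled path contains each nucleotide
once.  The default charges the overlap to the downstream node's prefix.
At a merge node (≥ 2 in-edges) whose predecessors all have out-degree 1
and enough remaining sequence, the overlap is charged to the
predecessors' suffixes instead: this places junction boundaries at their
precise biological location and fully consumes pure bridge arms (the
2k−2-long node spanning an exon-skipping junction becomes an **empty
node**, the graph's encoding of a skip isoform).  The two rules cannot
double-remove an overlap: predecessor-side charging requires out-degree
1, so a node's suffix is ceded only toward its unique successor, whose
prefix is then left intact.  Nodes with both multiple in- and multiple
out-edges keep the default prefix trim and are flagged unadjusted.
Spelling conservation along every path is asserted in the tests.

### Junction signatures and their matching

Each edge yields a 2k signature: the k adjusted nucleotides on either
side of the node boundary, extended through unique neighbours when a
node's adjusted sequence is short.  Matching against annotated windows is
*occurrence-based*: a 2k window matches an edge if it occurs, in either
orientation and with ≤ 3 mismatches, anywhere in the edge's spelled
context **spanning the boundary**.  Position-rigid comparison would be
wrong: when alternative exons happen to share their first or last bases
(probability ~1/4 per base for random sequence), the graph's divergence
point sits a few bases away from the annotated splice site even though
the assembly is perfect.

### De novo RPKM

A read contributes one count to every node of which it contains at least
one k-mer (both orientations tried, at most once per node).  RPKM uses
the pre-adjustment node length — so empty nodes keep a meaningful value —
and the library's total trimmed read count as the per-million
denominator (reads that trim to zero length still count as sequenced
reads; a flag excludes them).  A TPM-like column rescales each library's
RPKM to sum to 10^6 over nodes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 25 | k-mer length (vertices); edges are (k+1)-mers |
| c | 3 | coverage cutoff on summed k-mer counts, applied pre-graph |
| c2 | max(2, 20·Gb) | paired-edge count cutoff |
| k0 | 12 | starting mer length of the iterative enumeration |
| qmin | 15 | trim each read at the first base with phred < qmin |
| tip_len | 2k | dead-end removal threshold (spelled nt) |
| bubble_max_mismatch | 2 | per-branch-pair mismatch allowance |
| min_graph_len | 100 | longest-path filter on emitted graphs (nt) |

Larger datasets want larger k and much larger c; the defaults suit the
simulated workstation-scale datasets used throughout the tests.

## The simulator

The generator produces what the assembler is designed to recover: genes
of 2–4 exons (flanking exons ≥ 2k nt so bubbles are resolvable), optional
skipped internal exons, biallelic SNPs placed ≥ k from exon boundaries,
per-library lognormal expression (μ=1, σ=0.8), and non-strand-specific
2×100 nt paired-end reads with normal insert sizes (250 ± 30) and
substitution errors (0.5% by default; no indels, matching the
substitution-driven tip/bubble model).  Truth tables record the 2k
windows around every exon adjacency not shared by all of a gene's
isoforms, and per-transcript sampled read counts.

Fragment starts are drawn so that transcript-terminal fragments occur
(fragments clipped at position 0 or at the transcript end), as physical
shearing of a molecule produces.  A purely interior-uniform start model
leaves transcript ends at a small fraction of interior coverage, below
any reasonable cutoff, and end k-mers would always be lost — full-length
recovery would be impossible for *any* assembler, which is a property of
that read model, not of assembly.

What the simulator does **not** model: intron retention and complex
event grammars, indels, instrument-specific error/quality profiles,
positional coverage bias, and sequence composition bias.  Passing tests
therefore demonstrate the algorithmic contracts (exact counting, cutoff
semantics, structure recovery, expression fidelity) on clean alternative
splicing structure, not robustness to every artifact of real libraries.

## Numerical and determinism choices

* Phred encoding fixed to +33.
* Counts are exact integers throughout; RPKM/TPM are printed at 4
  decimals.
* All randomness flows through a single seeded generator per experiment;
  node ids, graph ids, FASTA/TSV ordering, and the run log are fully
  deterministic, so identical inputs produce byte-identical outputs (the
  incremental-update guarantee is tested as byte equality).
* Degenerate inputs: empty libraries yield empty tables; reads shorter
  than k+1 contribute no edges; isolated cycles collapse to one node with
  a self-loop and are swept into the SCC handling; palindromic nodes are
  treated as forward–backward tangles.

## Problem sizes

The test suite and the acceptance script run simulations of 1–100 genes
at 25–50× coverage (10³–10⁴ read pairs per library, k ∈ {15, 25, 31}),
sizes at which every stage's output can be checked against brute-force
oracles (dictionary k-mer counts, pairwise-reachability SCCs, substring
read recounts) exactly.

## Known limitations

* The sequential stage holds the cutoff graph and per-library read sets
  in memory; the two-stage memory discipline is architectural here
  (per-library archives, pre-graph cutoff), not an out-of-core
  implementation.
* On error-bearing data, recurrent substitution errors near true branch
  points create unequal-length bubbles that survive cleaning and appear
  as unannotated junctions; with a 0.5% error rate at 30× the mixed-run
  junction specificity is ~70%, rising to 100% on error-free input under
  identical conditions (the acceptance script reports the error-bearing
  number).
* Paired edges annotate the graphs; they are not used to thread
  transcripts or scaffold across components.
* Expression is per-node; multi-mapping reads contribute to every node
  sharing a k-mer, with no EM-style reassignment.
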