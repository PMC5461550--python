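import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spliceasm.dbg import build_graph, merge_tables
from spliceasm.kmercount import count_library, revcomp
from spliceasm.readio import Library

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1235)


def rand_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def naive_kmer_count(reads, k: int) -> dict[str, int]:
    """Independent dictionary-count oracle over both strands, skipping N."""
    counts: dict[str, int] = {}
    for r in reads:
        for s in (r, revcomp(r)):
            for i in range(len(s) - k + 1):
                mer = s[i : i + k]
                if "N" not in mer:
                    counts[mer] = counts.get(mer, 0) + 1
    return counts


def tile_reads(seq: str, read_len: int = 70, step: int = 5) -> list[str]:
    """Reads tiling a sequence end to end (uniform deep coverage)."""
    if len(seq) <= read_len:
        return [seq]
    out = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    if (len(seq) - read_len) % step:
        out.append(seq[-read_len:])
    return out


def graph_from_seqs(seqs, k: int, read_len: int = 70, step: int = 5, c: int = 1):
    """Collapsed de Bruijn graph from tiling reads over the given sequences."""
    reads = [r for s in seqs for r in tile_reads(s, read_len, step)]
    lib = Library.from_sequences("fix", reads)
    tk, tk1 = count_library(lib, k)
    return build_graph(merge_tables([tk], c), merge_tables([tk1], c))
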