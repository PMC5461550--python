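"""Stage-1 k-mer counting: encoding, iterative extension, serialization."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spliceasm.kmercount import (
    FrequencyTable,
    count_library,
    decode_mer,
    encode_mer,
    export_tsv,
    extend_table,
    init_table,
    load_table,
    revcomp,
    save_table,
)
from spliceasm.readio import Library

from .conftest import naive_kmer_count, rand_seq


def test_encode_examples():
    assert encode_mer("AAA") == 0
    assert encode_mer("ACG") == 6
    with pytest.raises(ValueError):
        encode_mer("ACN")


def test_decode_inverts_encode_for_all_3mers():
    for mer in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
        assert decode_mer(encode_mer(mer), 3) == mer


def test_integer_order_is_lexicographic():
    mers = ["".join(t) for t in itertools.product("ACGT", repeat=4)]
    codes = [encode_mer(m) for m in mers]
    assert codes == sorted(codes)
    assert mers == sorted(mers)


def test_init_table_examples():
    assert init_table(Library.from_sequences("a", ["AAC"]), 2).to_dict() == {
        "AA": 1, "AC": 1, "GT": 1, "TT": 1
    }
    assert init_table(Library.from_sequences("e", []), 5).to_dict() == {}
    assert init_table(Library.from_sequences("b", ["AAAA"]), 3).to_dict() == {
        "AAA": 2, "TTT": 2
    }


def test_init_table_rejects_large_k0():
    with pytest.raises(ValueError):
        init_table(Library.from_sequences("a", ["AAC"]), 32)


def test_extend_examples():
    lib = Library.from_sequences("a", ["AAC"])
    t2 = init_table(lib, 2)
    assert extend_table(t2, lib).to_dict() == {"AAC": 1, "GTT": 1}
    empty = init_table(Library.from_sequences("e", []), 2)
    assert extend_table(empty, lib).to_dict() == {}


def test_extend_rejects_unsorted_table():
    bad = FrequencyTable(2, np.array([5, 1], dtype=np.uint64),
                         np.array([1, 1], dtype=np.int64))
    with pytest.raises(ValueError, match="sorted"):
        extend_table(bad, Library.from_sequences("a", ["AAC"]))


@pytest.mark.parametrize("k", [15, 25])
def test_extension_chain_equals_naive_count(rng, k):
    reads = [rand_seq(rng, int(n)) for n in rng.integers(40, 120, 60)]
    # sprinkle N: mers containing N must be skipped entirely
    reads[0] = reads[0][:10] + "N" + reads[0][11:]
    lib = Library.from_sequences("r", reads)
    tk, tk1 = count_library(lib, k, k0=12)
    assert tk.to_dict() == naive_kmer_count(reads, k)
    assert tk1.to_dict() == naive_kmer_count(reads, k + 1)


def test_big_mer_path_equals_naive_count(rng):
    """Mer lengths beyond the 64-bit fast path use the same semantics."""
    reads = [rand_seq(rng, 60) for _ in range(8)]
    lib = Library.from_sequences("r", reads)
    k = 35
    tk, tk1 = count_library(lib, k, k0=12)
    assert not tk.is_fast and not tk1.is_fast
    assert tk.to_dict() == naive_kmer_count(reads, k)
    assert tk1.to_dict() == naive_kmer_count(reads, k + 1)


def test_strand_closure_and_pruning(rng):
    reads = [rand_seq(rng, 80) for _ in range(30)]
    lib = Library.from_sequences("r", reads)
    table = init_table(lib, 12)
    prev_n = len(table)
    occurrences_bound = sum(2 * max(0, len(r) - 12) for r in reads)
    for _ in range(4):
        table = extend_table(table, lib)
        d = table.to_dict()
        # strand closure: reverse complement present with equal count
        assert all(d[revcomp(m)] == c for m, c in d.items())
        # pruning monotonicity
        assert len(table) <= 4 * prev_n
        # conservation: total occurrences bounded by available positions
        assert sum(d.values()) <= occurrences_bound
        prev_n = len(table)


def test_read_shorter_than_k_contributes_nothing():
    lib = Library.from_sequences("s", ["ACGTACGT"])
    tk, tk1 = count_library(lib, 8, k0=4)
    assert sum(tk.counts) == 2  # forward + reverse strand of the full read
    assert len(tk1) == 0


def test_reuse_from_stored_smaller_k(rng, tmp_path):
    reads = [rand_seq(rng, 90) for _ in range(40)]
    lib = Library.from_sequences("r", reads)
    tk_small, _ = count_library(lib, 21, k0=12)
    path = tmp_path / "r.k21.skt"
    save_table(tk_small, str(path))
    tk_a, tk1_a = count_library(lib, 25, start_table=load_table(str(path)))
    tk_b, tk1_b = count_library(lib, 25, k0=12)
    assert tk_a.to_dict() == tk_b.to_dict()
    assert tk1_a.to_dict() == tk1_b.to_dict()


def test_archive_roundtrip_and_tsv(rng, tmp_path):
    reads = [rand_seq(rng, 60) for _ in range(10)]
    lib = Library.from_sequences("mylib", reads)
    tk, _ = count_library(lib, 17, k0=12)
    p = tmp_path / "t.skt"
    save_table(tk, str(p))
    back = load_table(str(p))
    assert back.k_len == 17
    assert back.library == "mylib"
    assert back.to_dict() == tk.to_dict()
    tsv = tmp_path / "t.tsv"
    export_tsv(tk, str(tsv))
    lines = tsv.read_text().splitlines()
    assert len(lines) == len(tk)
    mers = [ln.split("\t")[0] for ln in lines]
    assert mers == sorted(mers)


def test_archive_rejects_wrong_magic(tmp_path):
    p = tmp_path / "bad.skt"
    p.write_bytes(b"NOPE" + b"\0" * 20)
    with pytest.raises(ValueError, match="archive"):
        load_table(str(p))


@given(st.lists(st.text(alphabet="ACGT", min_size=12, max_size=40), max_size=12))
def test_chain_property_matches_naive(reads):
    lib = Library.from_sequences("h", reads)
    tk, tk1 = count_library(lib, 9, k0=6)
    assert tk.to_dict() == naive_kmer_count(reads, 9)
    assert tk1.to_dict() == naive_kmer_count(reads, 10)
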