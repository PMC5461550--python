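"""Stage-1 per-library k-mer frequency enumeration by iterative extension.

Each k'-mer is encoded in 2 bits per base (A=0, C=1, G=2, T=3,
most-significant first) so that integer order equals lexicographic order.
Counting starts at a moderate k0 (default 12) where every occurring k0-mer
is enumerated directly, then iterates: given the sorted table of k'-mers,
an array of 4n slots (one per possible final nucleotide of each table
entry) is filled in a single pass over the reads by binary-searching each
(k'+1)-mer's k'-prefix; zero-count slots are pruned, yielding the sorted
(k'+1)-mer table.  The chain stops once both the k-mer table (graph
vertices) and the (k+1)-mer table (edge support) are available.

Both the forward and the reverse-complement orientation of every read are
scanned, and both oriented mers are stored — no canonicalization — because
the downstream graph deliberately carries forward and backward nodes.
k-mers containing N are skipped (2-bit alphabet).

Tables with mer length <= 32 use a vectorized uint64 fast path; longer
mers (up to 63) fall back to arbitrary-precision Python integers with the
same semantics.
"""

from __future__ import annotations

import struct
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

MAX_K = 63  # 2 bits/base in a 128-bit code
_FAST_K = 32  # codes fit a uint64

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_RC = str.maketrans("ACGTN", "TGCAN")

_ENC_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _ENC_LUT[_b] = _v
_DEC_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def encode_mer(seq: str) -> int:
    """2-bit integer code of a mer; raises ValueError on non-ACGT."""
    if len(seq) > MAX_K:
        raise ValueError(f"mer longer than {MAX_K}: {len(seq)}")
    code = 0
    for ch in seq:
        v = _CODE.get(ch)
        if v is None:
            raise ValueError(f"non-ACGT character {ch!r} in mer")
        code = (code << 2) | v
    return code


def decode_mer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def decode_mers(codes: np.ndarray, k: int) -> list[str]:
    """Vectorized decode of a uint64 code array."""
    if len(codes) == 0:
        return []
    shifts = (2 * (k - 1 - np.arange(k))).astype(np.uint64)
    mat = (codes.astype(np.uint64)[:, None] >> shifts[None, :]) & np.uint64(3)
    raw = _DEC_LUT[mat.astype(np.uint8)].tobytes()
    return [raw[i * k : (i + 1) * k].decode() for i in range(len(codes))]


@dataclass
class FrequencyTable:
    """Sorted table of integer-coded k'-mers with occurrence counts.

    ``codes`` is a strictly increasing uint64 array for k_len <= 32, else a
    strictly increasing list of Python ints.
    """

    k_len: int
    codes: Union[np.ndarray, list[int]]
    counts: np.ndarray
    library: str = ""

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def is_fast(self) -> bool:
        return isinstance(self.codes, np.ndarray)

    def check_sorted(self) -> None:
        if self.is_fast:
            if len(self.codes) > 1 and not np.all(self.codes[1:] > self.codes[:-1]):
                raise ValueError("frequency table codes are not strictly sorted")
        else:
            if any(a >= b for a, b in zip(self.codes, self.codes[1:])):
                raise ValueError("frequency table codes are not strictly sorted")

    def to_dict(self) -> dict[str, int]:
        """Mer-string -> count mapping (testing/debugging)."""
        if self.is_fast:
            mers = decode_mers(self.codes, self.k_len)
        else:
            mers = [decode_mer(c, self.k_len) for c in self.codes]
        return {m: int(c) for m, c in zip(mers, self.counts)}

    def get(self, mer: str) -> int:
        code = encode_mer(mer)
        if self.is_fast:
            i = int(np.searchsorted(self.codes, np.uint64(code)))
            if i < len(self.codes) and int(self.codes[i]) == code:
                return int(self.counts[i])
        else:
            i = bisect_left(self.codes, code)
            if i < len(self.codes) and self.codes[i] == code:
                return int(self.counts[i])
        return 0


def _empty_table(k_len: int, library: str) -> FrequencyTable:
    codes = np.empty(0, dtype=np.uint64) if k_len <= _FAST_K else []
    return FrequencyTable(k_len, codes, np.empty(0, dtype=np.int64), library)


def _sequences(library) -> list[str]:
    if hasattr(library, "sequences"):
        return list(library.sequences())
    return list(library)


def _lib_name(library) -> str:
    return getattr(library, "name", "")


def _encoded_stream(seqs: Sequence[str]) -> np.ndarray:
    """All reads, forward then reverse complement, separated by sentinel 4."""
    parts = []
    for s in seqs:
        a = _ENC_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]
        parts.append(a)
        parts.append(np.array([4], dtype=np.uint8))
        parts.append((np.uint8(3) - a[::-1]) % np.uint8(8))  # 3-x for bases, 4 stays >3
        parts.append(np.array([4], dtype=np.uint8))
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts)


def _window_codes(arr: np.ndarray, w: int) -> np.ndarray:
    """uint64 codes of every valid (non-N, non-separator) window of width w."""
    m = arr.size - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    code = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(w):
        seg = arr[j : j + m]
        bad |= seg > 3
        code = (code << np.uint64(2)) | seg.astype(np.uint64)
    return code[~bad]


def init_table(library, k0: int) -> FrequencyTable:
    """Counts of every k0-mer of the library, both orientations.

    Conceptually the complete 4^k0 space with zero-count entries pruned;
    k0 > 31 is rejected (initial space too large).
    """
    if not 1 <= k0 <= 31:
        raise ValueError(f"k0 must be in [1, 31], got {k0}")
    seqs = _sequences(library)
    arr = _encoded_stream(seqs)
    codes = _window_codes(arr, k0)
    if codes.size == 0:
        return _empty_table(k0, _lib_name(library))
    vals, counts = np.unique(codes, return_counts=True)
    return FrequencyTable(k0, vals, counts.astype(np.int64), _lib_name(library))


def extend_table(table: FrequencyTable, library) -> FrequencyTable:
    """One extension step: the (k'+1)-mer table from the k'-mer table.

    Allocates the 4n slot array, fills it by binary search of each
    (k'+1)-mer's prefix over one pass of the reads (both orientations),
    and prunes zero slots.
    """
    w = table.k_len + 1
    if w > MAX_K:
        raise ValueError(f"extension beyond mer length {MAX_K}")
    table.check_sorted()
    n = len(table)
    lib_name = _lib_name(library) or table.library
    if n == 0:
        return _empty_table(w, lib_name)
    seqs = _sequences(library)

    if w <= _FAST_K:
        arr = _encoded_stream(seqs)
        wc = _window_codes(arr, w)
        prefix = wc >> np.uint64(2)
        last = (wc & np.uint64(3)).astype(np.int64)
        idx = np.searchsorted(table.codes, prefix)
        idx_c = np.minimum(idx, n - 1)
        ok = table.codes[idx_c] == prefix
        slots = np.bincount(idx_c[ok] * 4 + last[ok], minlength=4 * n)
        nz = np.nonzero(slots)[0]
        new_codes = (table.codes[nz // 4] << np.uint64(2)) | (nz % 4).astype(np.uint64)
        return FrequencyTable(w, new_codes, slots[nz].astype(np.int64), lib_name)

    # big-mer path: arbitrary-precision codes, bisect per position
    codes_l = table.codes.tolist() if table.is_fast else table.codes
    slots = np.zeros(4 * n, dtype=np.int64)
    mask = (1 << (2 * w)) - 1
    for s in seqs:
        for seq in (s, revcomp(s)):
            code = 0
            valid = 0
            for ch in seq:
                v = _CODE.get(ch)
                if v is None:
                    code = 0
                    valid = 0
                    continue
                code = ((code << 2) | v) & mask
                valid += 1
                if valid >= w:
                    p = code >> 2
                    i = bisect_left(codes_l, p)
                    if i < n and codes_l[i] == p:
                        slots[4 * i + (code & 3)] += 1
    nz = np.nonzero(slots)[0]
    new_codes = [(codes_l[int(i) // 4] << 2) | (int(i) % 4) for i in nz]
    return FrequencyTable(w, new_codes, slots[nz], lib_name)


def count_library(
    library,
    k: int,
    k0: int = 12,
    start_table: FrequencyTable | None = None,
) -> tuple[FrequencyTable, FrequencyTable]:
    """Iterate extension from k0 (or a stored smaller-k table) to k and k+1.

    Returns the k-mer table (graph vertices) and the (k+1)-mer table (edge
    support).  ``start_table`` allows reuse of a previously computed table
    at a smaller mer length, which yields identical results to a
    from-scratch run.
    """
    if start_table is not None:
        if start_table.k_len > k:
            raise ValueError("start_table mer length exceeds target k")
        table = start_table
    else:
        table = init_table(library, min(k0, k))
    while table.k_len < k:
        table = extend_table(table, library)
    edge_table = extend_table(table, library)
    return table, edge_table


# ---------------------------------------------------------------------------
# stage-1 archive serialization

_MAGIC = b"SKT1"
_VERSION = 1


def save_table(table: FrequencyTable, path: str) -> None:
    """Binary stage-1 archive: header + n records of (16-byte code, u32 count)."""
    name = table.library.encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BBQH", _VERSION, table.k_len, len(table), len(name)))
        fh.write(name)
        counts = table.counts
        if np.any(counts >= 2**32):
            raise ValueError("count exceeds 32-bit archive record")
        codes = table.codes if not table.is_fast else table.codes.tolist()
        for code, cnt in zip(codes, counts):
            fh.write(int(code).to_bytes(16, "little"))
            fh.write(struct.pack("<I", int(cnt)))


def load_table(path: str) -> FrequencyTable:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a stage-1 k-mer archive")
        version, k_len, n, name_len = struct.unpack("<BBQH", fh.read(12))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported archive version {version}")
        name = fh.read(name_len).decode()
        codes: list[int] = []
        counts = np.empty(n, dtype=np.int64)
        for i in range(n):
            rec = fh.read(20)
            if len(rec) != 20:
                raise ValueError(f"{path}: truncated archive")
            codes.append(int.from_bytes(rec[:16], "little"))
            counts[i] = struct.unpack("<I", rec[16:])[0]
    arr: Union[np.ndarray, list[int]]
    if k_len <= _FAST_K:
        arr = np.array(codes, dtype=np.uint64)
    else:
        arr = codes
    return FrequencyTable(k_len, arr, counts, name)


def export_tsv(table: FrequencyTable, path: str) -> None:
    """Plain-text ``mer<TAB>count`` export, lexicographically sorted."""
    with open(path, "w") as fh:
        for mer, cnt in table.to_dict().items():
            fh.write(f"{mer}\t{cnt}\n")
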