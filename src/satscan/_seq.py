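"""Low-level nucleotide encoding and k-mer code arithmetic.

Sequences are encoded as int8 arrays with A=0, C=1, G=2, T=3 and any other
character (N, ambiguity codes) as -1.  A k-mer starting at position i is
represented by the base-4 integer of its bases; windows containing a -1 are
marked invalid and carry no code.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to an int8 array (non-ACGT -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(arr: np.ndarray) -> str:
    """Decode an int8 base array back to a string (-1 -> N)."""
    out = np.where(arr >= 0, _BASES[np.clip(arr, 0, 3)], ord("N"))
    return out.astype(np.uint8).tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes and validity mask for every start position.

    Returns ``(codes, valid)`` of length ``len(arr) - k + 1``; ``codes`` is
    int64 and meaningful only where ``valid`` is True (window free of
    non-ACGT characters).  Empty arrays if the sequence is shorter than k.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = arr.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = a[j : j + n]
        codes = codes * 4 + np.maximum(window, 0)
        valid &= window >= 0
    return codes, valid


def revcomp_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complement of each k-length window of ``arr``."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    # complement of base b is 3-b; reading the window right-to-left.
    for j in range(k - 1, -1, -1):
        window = a[j : j + n]
        codes = codes * 4 + (3 - np.maximum(window, 0))
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical k-mer codes: min(forward, reverse-complement)."""
    fwd, valid = kmer_codes(arr, k)
    if len(fwd) == 0:
        return fwd, valid
    rc = revcomp_codes(arr, k)
    return np.minimum(fwd, rc), valid


def code_to_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = _BASES[code & 3]
        code >>= 2
    return out.decode("ascii")


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        b = _CODE[ord(ch)]
        if b < 0:
            raise ValueError(f"non-ACGT character in k-mer: {kmer!r}")
        code = code * 4 + int(b)
    return code
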