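"""Integer encoding of k-mers and vectorized Hamming-ball enumeration.

k-mers over {A,C,G,U} are encoded base-4 (A=0, C=1, G=2, U=3), most
significant digit first, so the lexicographic order of strings equals the
numeric order of codes. Windows containing N (or any other symbol) get
code -1 and are skipped by consumers.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb

import numpy as np

BASES = "ACGU"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * 4 + _BASE_CODE[ch]
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def seq_to_codes(seq: str) -> np.ndarray:
    """Per-base integer codes; non-ACGU symbols become 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def window_codes(seq: str, k: int) -> np.ndarray:
    """Codes of all k-length windows of ``seq``; -1 where a window has N."""
    base = seq_to_codes(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = base[j : j + n]
        codes = codes * 4 + np.where(col < 4, col, 0)
        valid &= col < 4
    codes[~valid] = -1
    return codes


def hamming_ball_size(k: int, radius: int) -> int:
    """|{x : d_H(x, root) <= radius}| = sum_i C(k,i)*3^i."""
    return sum(comb(k, i) * 3**i for i in range(radius + 1))


def hamming_ball_codes(codes: np.ndarray, k: int, radius: int) -> np.ndarray:
    """Hamming balls of an array of k-mer codes, vectorized.

    Returns an (n, ball_size) int64 array; row i holds every code within
    Hamming distance <= radius of codes[i] (the root itself first).
    """
    codes = np.asarray(codes, dtype=np.int64)
    cols = [codes]
    place = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] // place[None, :]) % 4  # (n, k)
    for r in range(1, radius + 1):
        for positions in combinations(range(k), r):
            for offsets in product((1, 2, 3), repeat=r):
                delta = np.zeros_like(codes)
                for pos, off in zip(positions, offsets):
                    d = digits[:, pos]
                    delta = delta + ((d + off) % 4 - d) * place[pos]
                cols.append(codes + delta)
    return np.stack(cols, axis=1)


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))
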