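"""Burrows–Wheeler transform, FM-index and mismatch-tolerant k-mer search.

The index supports exact backward search; inexact search enumerates the
Hamming ball of the root k-mer ("relatives") and searches each relative
exactly, which keeps the search exact-by-construction for small radii.

Multiple sequences are indexed as a single text joined by '#' separators
(lexicographically above the '$' sentinel, below the bases). Because
queries are drawn from {A,C,G,U}, no hit can straddle a separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kmercode import decode_kmer, encode_kmer, hamming_ball_codes

SENTINEL = "$"
SEPARATOR = "#"


def suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers), O(n log^2 n)."""
    n = len(text)
    rank = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    shift = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - shift] = rank[shift:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        ranks_sorted = np.cumsum(changed)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = ranks_sorted
        rank = new_rank
        sa = order
        if ranks_sorted[-1] == n - 1:
            return sa
        shift *= 2


def bwt_transform(text: str) -> str:
    """Last column of the sorted rotation matrix of ``text``.

    ``text`` must already end in a unique sentinel that sorts below every
    other symbol, which makes rotation sorting equivalent to suffix sorting.
    """
    if not text.endswith(SENTINEL):
        raise ValueError("text must end with the sentinel '$'")
    if SENTINEL in text[:-1]:
        raise ValueError("sentinel occurs inside the text")
    sa = suffix_array(text)
    return "".join(text[i - 1] for i in sa)


@dataclass
class FMIndex:
    """FM-index over a sentinel-terminated text.

    Stores the BWT, per-symbol cumulative counts of the first column
    (``first_column_ranks``), a checkpointed per-symbol occurrence table
    along the BWT (``occ_step`` spacing with on-the-fly completion), and
    the full suffix array for locating.
    """

    text: str
    occ_step: int = 32
    bwt: str = field(init=False)
    sa: np.ndarray = field(init=False)
    first_column_ranks: dict = field(init=False)
    _alphabet: list = field(init=False)
    _bwt_codes: np.ndarray = field(init=False)
    _checkpoints: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.text.endswith(SENTINEL):
            self.text = self.text + SENTINEL
        if SENTINEL in self.text[:-1]:
            raise ValueError("sentinel occurs inside the text")
        self.sa = suffix_array(self.text)
        self.bwt = "".join(self.text[i - 1] for i in self.sa)
        self._alphabet = sorted(set(self.text))
        sym_index = {c: i for i, c in enumerate(self._alphabet)}
        self._bwt_codes = np.array([sym_index[c] for c in self.bwt], dtype=np.int8)
        counts = np.bincount(self._bwt_codes, minlength=len(self._alphabet))
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        self.first_column_ranks = {c: int(starts[i]) for i, c in enumerate(self._alphabet)}
        # occurrence checkpoints: row j holds counts over bwt[:j*occ_step]
        one_hot = self._bwt_codes[:, None] == np.arange(len(self._alphabet))[None, :]
        cum = np.zeros((len(self.bwt) + 1, len(self._alphabet)), dtype=np.int64)
        np.cumsum(one_hot, axis=0, out=cum[1:])
        self._checkpoints = cum[:: self.occ_step].copy()
        self._sym_index = sym_index

    def _occ(self, symbol_code: int, i: int) -> int:
        """Occurrences of symbol in bwt[:i]."""
        row = i // self.occ_step
        count = int(self._checkpoints[row, symbol_code])
        for pos in range(row * self.occ_step, i):
            if self._bwt_codes[pos] == symbol_code:
                count += 1
        return count

    def backward_search(self, query: str) -> tuple[int, int]:
        """Half-open BWT-row range [lo, hi) of suffixes prefixed by ``query``."""
        if not query:
            raise ValueError("empty query")
        lo, hi = 0, len(self.bwt)
        for ch in reversed(query):
            code = self._sym_index.get(ch)
            if code is None:
                return (0, 0)
            base = self.first_column_ranks[ch]
            lo = base + self._occ(code, lo)
            hi = base + self._occ(code, hi)
            if lo >= hi:
                return (0, 0)
        return (lo, hi)

    def count(self, query: str) -> int:
        lo, hi = self.backward_search(query)
        return hi - lo

    def locate(self, query: str) -> set[int]:
        """0-based start positions of exact occurrences of ``query``."""
        lo, hi = self.backward_search(query)
        return {int(p) for p in self.sa[lo:hi]}


def fm_locate(index: FMIndex, query: str) -> set[int]:
    return index.locate(query)


def enumerate_relatives(root: str, max_mismatches: int) -> set[str]:
    """The Hamming ball of ``root``: every same-length k-mer over {A,C,G,U}
    within ``max_mismatches`` substitutions (the root included)."""
    k = len(root)
    if not 0 <= max_mismatches <= k:
        raise ValueError("max_mismatches must be in [0, k]")
    codes = hamming_ball_codes(np.array([encode_kmer(root)]), k, max_mismatches)[0]
    return {decode_kmer(int(c), k) for c in codes}


class MultiSequenceIndex:
    """FM-index over a set of sequences with per-sequence hit reporting."""

    def __init__(self, sequences: Sequence[str], ids: Sequence[str] | None = None):
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(sequences))]
        if len(self.ids) != len(sequences):
            raise ValueError("ids/sequences length mismatch")
        self.sequences = list(sequences)
        text = SEPARATOR.join(self.sequences)
        self.index = FMIndex(text) if text else None
        # offsets[i] = global start of sequence i in the joined text
        offsets = []
        pos = 0
        for s in self.sequences:
            offsets.append(pos)
            pos += len(s) + 1
        self._offsets = np.array(offsets, dtype=np.int64)
        self._lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)

    def _to_local(self, gpos: int, qlen: int):
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        local = gpos - int(self._offsets[i])
        if local + qlen > int(self._lengths[i]):
            return None  # would straddle a separator (cannot happen for ACGU queries)
        return i, local

    def locate(self, query: str) -> dict[str, list[int]]:
        """Exact per-sequence hit positions of ``query``."""
        hits: dict[str, list[int]] = {}
        if self.index is None:
            return hits
        for gpos in sorted(self.index.locate(query)):
            loc = self._to_local(gpos, len(query))
            if loc is None:
                continue
            i, local = loc
            hits.setdefault(self.ids[i], []).append(local)
        return hits

    def inexact_locate(self, root: str, max_mismatches: int) -> dict[str, list[int]]:
        """Union of exact hits over every relative of ``root``.

        Equals a naive per-sequence Hamming-distance scan at the same radius.
        """
        merged: dict[str, set[int]] = {}
        for relative in enumerate_relatives(root, max_mismatches):
            for sid, positions in self.locate(relative).items():
                merged.setdefault(sid, set()).update(positions)
        return {sid: sorted(pos) for sid, pos in merged.items()}


def inexact_locate(index: MultiSequenceIndex, root: str, max_mismatches: int
                   ) -> dict[str, list[int]]:
    return index.inexact_locate(root, max_mismatches)


def naive_hamming_scan(sequences: Mapping[str, str] | Sequence[str], root: str,
                       max_mismatches: int) -> dict[str, list[int]]:
    """Brute-force per-sequence scan; reference oracle for the FM path."""
    if not isinstance(sequences, Mapping):
        sequences = {str(i): s for i, s in enumerate(sequences)}
    k = len(root)
    out: dict[str, list[int]] = {}
    for sid, seq in sequences.items():
        positions = [
            i for i in range(len(seq) - k + 1)
            if sum(a != b for a, b in zip(seq[i : i + k], root)) <= max_mismatches
        ]
        if positions:
            out[sid] = positions
    return out
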