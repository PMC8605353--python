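"""Prime-motif discovery from cross-linking peak sequences.

The procedure enumerates all 4^6 6-mer seeds, counts for each seed the
peaks containing the seed or one of its Hamming-distance<=2 relatives,
tests enrichment against a length-matched random corpus with an exact
one-sided binomial test (p <= 0.01) plus a coverage rule (>= 70% of
peaks), expands significant seeds one base at a time on both sides while
coverage and identity stay above 70%, and selects the best expanded
family as the "prime motif". Residual peaks are mined recursively for
mutually-exclusive motifs down to 20% data representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kmercode import (
    BASES,
    decode_kmer,
    encode_kmer,
    hamming_ball_codes,
    seq_to_codes,
    window_codes,
)

DEFAULT_SEED_K = 6
DEFAULT_SEED_RADIUS = 2  # two mismatches at the 6-mer seed stage
MAX_MOTIF_LEN = 10


def mismatch_budget(k: int) -> int:
    """Mismatch allowance for a k-long consensus: 2 at the 6-mer seed
    stage, floor(0.3*k) (the 30%-mismatch rule) for expanded lengths."""
    return DEFAULT_SEED_RADIUS if k <= DEFAULT_SEED_K else int(0.3 * k)


@dataclass
class KmerSeedResult:
    """Enrichment result for one 6-mer seed family."""

    root: str
    radius: int
    x: int          # peaks containing root-or-relative
    n: int          # total peaks
    p0: float       # null occurrence probability from the random corpus
    pvalue: float   # one-sided binomial upper tail P(X >= x | n, p0)
    significant: bool

    @property
    def coverage(self) -> float:
        return self.x / self.n if self.n else 0.0


@dataclass
class PrimeMotif:
    """Expanded consensus motif with per-position base counts."""

    consensus: str
    pwm: np.ndarray               # (4, L) counts over A,C,G,U
    coverage: float
    matched_peak_ids: set
    kind: str = "primary"         # or "mutually_exclusive"
    pvalue: float = 1.0
    identity: float = 1.0         # mean per-instance identity of matches
    seed: Optional[str] = None

    def __post_init__(self) -> None:
        L = len(self.consensus)
        if not DEFAULT_SEED_K <= L <= MAX_MOTIF_LEN:
            raise ValueError(f"motif length {L} outside [6, 10]")
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (4, L):
            raise ValueError("pwm must be (4, motif length)")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def information(self) -> float:
        """Mean per-column information content of the PWM, in bits.

        High when the matched instances agree on each column; a column
        recruited from random context contributes ~0 bits, so trimmed,
        shifted or overshot variants of a true consensus score lower.
        """
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0)), 0.0)
        ic_per_col = 2.0 + (f * logf).sum(axis=0)
        return float(ic_per_col.mean())

    @property
    def score(self) -> tuple:
        """Ranking key: abundance x column information, then length,
        then enrichment."""
        neg_log_p = -np.log10(max(self.pvalue, 1e-300))
        return (self.coverage * self.information, len(self.consensus), neg_log_p)

    @property
    def frequencies(self) -> np.ndarray:
        colsum = self.pwm.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return self.pwm / colsum


def enumerate_seed_spectrum(k: int = DEFAULT_SEED_K) -> list[str]:
    """All 4^k k-mers over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


def seed_presence_counts(sequences: Sequence[str], k: int, radius: int) -> np.ndarray:
    """counts[s] = number of sequences containing seed s or a relative.

    A sequence "contains" seed s iff one of its k-windows lies within
    Hamming distance <= radius of s — symmetric, so the count is obtained
    by expanding each observed window's Hamming ball.
    """
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        codes = window_codes(seq, k)
        codes = np.unique(codes[codes >= 0])
        if codes.size == 0:
            continue
        ball = hamming_ball_codes(codes, k, radius)
        counts[np.unique(ball)] += 1
    return counts


def null_probability(seed: str, random_corpus: Sequence[str], radius: int) -> float:
    """Fraction of random sequences containing seed-or-relative.

    Zero counts are floored at the pseudo-probability 1/(2*|corpus|)
    (and full counts symmetrically capped) so the binomial test is
    always defined.
    """
    if not random_corpus:
        raise ValueError("empty random corpus")
    counts = seed_presence_counts(random_corpus, len(seed), radius)
    m = len(random_corpus)
    frac = counts[encode_kmer(seed)] / m
    return float(np.clip(frac, 1.0 / (2 * m), 1.0 - 1.0 / (2 * m)))


def binomial_enrichment_pvalue(x, n, p0):
    """Exact one-sided upper tail P(X >= x | n, p0); vectorized."""
    return stats.binom.sf(np.asarray(x) - 1, n, p0)


def seed_enrichment(peaks: Sequence[str], seed: str, radius: int, p0: float,
                    p_cutoff: float = 0.01, min_coverage: float = 0.70,
                    ) -> KmerSeedResult:
    """Binomial over-representation test of one seed family against p0."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    counts = seed_presence_counts(peaks, len(seed), radius)
    x = int(counts[encode_kmer(seed)])
    n = len(peaks)
    pvalue = float(binomial_enrichment_pvalue(x, n, p0))
    significant = pvalue <= p_cutoff and (x / n if n else 0.0) >= min_coverage
    return KmerSeedResult(seed, radius, x, n, p0, pvalue, significant)


class ConsensusScanner:
    """Vectorized minimum-mismatch search of a consensus across peaks.

    Sequences are padded into one int8 matrix; pads and Ns always count
    as mismatches, so matches never extend past a sequence end.
    """

    PAD = 5

    def __init__(self, sequences: Sequence[str]):
        self.n = len(sequences)
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        lmax = int(self.lengths.max()) if self.n else 0
        self.matrix = np.full((self.n, lmax), self.PAD, dtype=np.int8)
        for i, s in enumerate(sequences):
            codes = seq_to_codes(s)
            codes[codes == 4] = self.PAD  # N counts as mismatch
            self.matrix[i, : len(s)] = codes

    def best_matches(self, consensus: str, budget: int):
        """Per sequence: (matched mask, best position, mismatches there).

        Best = fewest mismatches, leftmost on ties. Unmatched sequences
        get position -1.
        """
        k = len(consensus)
        cons = seq_to_codes(consensus)
        w = self.matrix.shape[1] - k + 1
        if self.n == 0 or w <= 0:
            return (np.zeros(self.n, dtype=bool),
                    np.full(self.n, -1, dtype=np.int64),
                    np.full(self.n, k, dtype=np.int64))
        mm = np.zeros((self.n, w), dtype=np.int16)
        for j in range(k):
            mm += self.matrix[:, j : j + w] != cons[j]
        best_pos = np.argmin(mm, axis=1)
        best_mm = mm[np.arange(self.n), best_pos]
        matched = best_mm <= budget
        pos = np.where(matched, best_pos, -1)
        return matched, pos, best_mm.astype(np.int64)

    def all_matches(self, consensus: str, budget: int) -> dict[int, list[int]]:
        """Every matching window position per sequence (naive-scan semantics)."""
        k = len(consensus)
        cons = seq_to_codes(consensus)
        w = self.matrix.shape[1] - k + 1
        out: dict[int, list[int]] = {}
        if self.n == 0 or w <= 0:
            return out
        mm = np.zeros((self.n, w), dtype=np.int16)
        for j in range(k):
            mm += self.matrix[:, j : j + w] != cons[j]
        rows, cols = np.nonzero(mm <= budget)
        for r, c in zip(rows.tolist(), cols.tolist()):
            out.setdefault(r, []).append(c)
        return out

    def flank_column(self, positions: np.ndarray, offset: int) -> np.ndarray:
        """Base codes at position+offset for matched sequences; 4 when the
        column falls outside the sequence."""
        col = positions + offset
        valid = (positions >= 0) & (col >= 0) & (col < self.lengths)
        out = np.full(self.n, 4, dtype=np.int8)
        rows = np.nonzero(valid)[0]
        vals = self.matrix[rows, col[valid]]
        vals = np.where(vals <= 3, vals, 4).astype(np.int8)
        out[rows] = vals
        return out


def _majority_base(codes: np.ndarray) -> Optional[str]:
    """Majority base among codes 0..3 (ties broken A<C<G<U); None if no
    sequence contributes a flanking base."""
    counts = np.bincount(codes[codes <= 3], minlength=4)
    if counts.sum() == 0:
        return None
    return BASES[int(np.argmax(counts))]  # argmax takes first max: A<C<G<U


def _pwm_from_matches(scanner: ConsensusScanner, positions: np.ndarray,
                      k: int) -> np.ndarray:
    pwm = np.zeros((4, k), dtype=float)
    for j in range(k):
        col = scanner.flank_column(positions, j)
        pwm[:, j] = np.bincount(col[col <= 3], minlength=4)[:4]
    return pwm


def expand_seed(seed_result: KmerSeedResult, peaks: Sequence[str],
                min_coverage: float = 0.70, min_identity: float = 0.70,
                max_len: int = MAX_MOTIF_LEN,
                max_loss_fraction: Optional[float] = None,
                scanner: Optional[ConsensusScanner] = None,
                total_n: Optional[int] = None) -> PrimeMotif:
    """Grow a significant seed one base at a time on both sides.

    Each round attempts a left then a right 1-nt extension with the
    majority base of the aligned flanking column; an extension is kept
    only while coverage stays >= min_coverage and the mean per-instance
    identity stays >= min_identity (and, when ``max_loss_fraction`` is
    set, while fewer than that fraction of matched instances are lost).
    Stops at length ``max_len`` or when both extensions fail.
    """
    scanner = scanner if scanner is not None else ConsensusScanner(list(peaks))
    n = total_n if total_n is not None else scanner.n
    consensus = seed_result.root
    matched, pos, mm = scanner.best_matches(consensus, mismatch_budget(len(consensus)))
    if not matched.any():
        raise ValueError(f"seed {consensus} not found in any peak")

    def try_extension(cand: str, new_col: int):
        m, p, d = scanner.best_matches(cand, mismatch_budget(len(cand)))
        cov = m.sum() / n
        if cov < min_coverage:
            return None
        identity = 1.0 - d[m].mean() / len(cand)
        if identity < min_identity:
            return None
        # the added column itself must be conserved: its base has to match
        # in >= min_identity of the aligned matched instances, otherwise
        # the extension is recruiting random context
        col = scanner.flank_column(np.where(m, p, -1), new_col)
        agree = (col == seq_to_codes(cand[new_col])[0]).sum()
        if m.sum() == 0 or agree / m.sum() < min_identity:
            return None
        if max_loss_fraction is not None and matched.sum() > 0:
            lost = (matched & ~m).sum() / matched.sum()
            if lost >= max_loss_fraction:
                return None
        return m, p, d

    def refine(consensus, matched, pos, mm):
        # refine to the fixed point of consensus <- PWM majority: the
        # expanded anchor may carry a noise-selected base; the family
        # consensus is the per-column majority of the matched instances
        for _ in range(5):
            pwm = _pwm_from_matches(scanner, np.where(matched, pos, -1),
                                    len(consensus))
            majority = "".join(BASES[i] for i in pwm.argmax(axis=0))
            if majority == consensus:
                break
            m2, p2, d2 = scanner.best_matches(majority,
                                              mismatch_budget(len(majority)))
            if m2.sum() / n < min_coverage:
                break
            consensus, matched, pos, mm = majority, m2, p2, d2
        return consensus, matched, pos, mm

    for _ in range(2 * max_len):
        grew = False
        if len(consensus) < max_len:
            # left extension
            base = _majority_base(
                scanner.flank_column(np.where(matched, pos, -1), -1))
            if base is not None:
                res = try_extension(base + consensus, 0)
                if res is not None:
                    consensus = base + consensus
                    matched, pos, mm = res
                    grew = True
        if len(consensus) < max_len:
            # right extension
            base = _majority_base(
                scanner.flank_column(np.where(matched, pos, -1), len(consensus)))
            if base is not None:
                res = try_extension(consensus + base, len(consensus))
                if res is not None:
                    consensus = consensus + base
                    matched, pos, mm = res
                    grew = True
        before = consensus
        consensus, matched, pos, mm = refine(consensus, matched, pos, mm)
        if not grew and consensus == before:
            break

    pwm = _pwm_from_matches(scanner, np.where(matched, pos, -1), len(consensus))
    identity = float(1.0 - mm[matched].mean() / len(consensus)) if matched.any() else 0.0
    return PrimeMotif(
        consensus=consensus,
        pwm=pwm,
        coverage=matched.sum() / n,
        matched_peak_ids=set(np.nonzero(matched)[0].tolist()),
        pvalue=seed_result.pvalue,
        identity=identity,
        seed=seed_result.root,
    )


def select_prime(expanded: Sequence[PrimeMotif]) -> PrimeMotif:
    """Best motif by (coverage x identity, length, -log p), with a
    deterministic alphabetical tie-break on the consensus."""
    if not expanded:
        raise ValueError("no candidate motifs")
    return sorted(
        expanded,
        key=lambda m: (-m.score[0], -m.score[1], -m.score[2], m.consensus),
    )[0]


def consensus_identity(a: str, b: str, min_overlap: int = 4) -> float:
    """Best-offset ungapped identity between two consensus strings,
    normalized by the shorter length; offsets with overlap < min_overlap
    are skipped."""
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    denom = len(a)
    for shift in range(-len(a) + min_overlap, len(b) - min_overlap + 1):
        matches = 0
        for i, ch in enumerate(a):
            j = i + shift
            if 0 <= j < len(b) and b[j] == ch:
                matches += 1
        best = max(best, matches / denom)
    return best


def cluster_prime_motifs(motifs: Sequence[PrimeMotif], min_similarity: float = 0.70
                         ) -> list[list[int]]:
    """Single-linkage clusters over best-offset consensus identity.

    Returns lists of indices into ``motifs``; order is deterministic
    (clusters by smallest member index).
    """
    if not motifs:
        raise ValueError("no motifs to cluster")
    n = len(motifs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if consensus_identity(motifs[i].consensus, motifs[j].consensus) >= min_similarity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def find_mutually_exclusive(peaks: Sequence[str], already_covered_ids: set,
                            null_corpus: Sequence[str],
                            min_fraction: float = 0.20,
                            p_cutoff: float = 0.01,
                            min_identity: float = 0.70,
                            max_expand: int = 40,
                            max_rounds: int = 8) -> list[PrimeMotif]:
    """Recursively mine residual (uncovered) peaks for further motifs.

    Each round runs the seed->enrich->expand cycle on the residual; a
    motif is kept while it still represents >= min_fraction of the
    ORIGINAL peak count. Expansion steps that would lose >= 10% of the
    matched data are skipped.
    """
    total_n = len(peaks)
    covered = set(already_covered_ids)
    found: list[PrimeMotif] = []
    null_counts = seed_presence_counts(null_corpus, DEFAULT_SEED_K, DEFAULT_SEED_RADIUS)
    m = len(null_corpus)
    p0 = np.clip(null_counts / m, 1.0 / (2 * m), 1.0 - 1.0 / (2 * m))

    for _ in range(max_rounds):
        residual_idx = [i for i in range(total_n) if i not in covered]
        if len(residual_idx) < min_fraction * total_n:
            break
        residual = [peaks[i] for i in residual_idx]
        counts = seed_presence_counts(residual, DEFAULT_SEED_K, DEFAULT_SEED_RADIUS)
        pvals = binomial_enrichment_pvalue(counts, len(residual), p0)
        # candidate seeds must alone still represent min_fraction of ALL peaks
        ok = (pvals <= p_cutoff) & (counts >= min_fraction * total_n)
        if not ok.any():
            break
        order = np.lexsort((pvals[ok], -counts[ok]))
        cand_codes = np.nonzero(ok)[0][order][:max_expand]
        scanner = ConsensusScanner(residual)
        candidates = []
        for code in cand_codes:
            seed = decode_kmer(int(code), DEFAULT_SEED_K)
            sr = KmerSeedResult(seed, DEFAULT_SEED_RADIUS, int(counts[code]),
                                len(residual), float(p0[code]),
                                float(pvals[code]), True)
            try:
                motif = expand_seed(
                    sr, residual, min_coverage=min_fraction * total_n / len(residual),
                    min_identity=min_identity, max_loss_fraction=0.10,
                    scanner=scanner)
            except ValueError:
                continue
            candidates.append(motif)
        if not candidates:
            break
        best = select_prime(candidates)
        matched_original = {residual_idx[i] for i in best.matched_peak_ids}
        if len(matched_original) < min_fraction * total_n:
            break
        best.kind = "mutually_exclusive"
        best.matched_peak_ids = matched_original
        best.coverage = len(matched_original) / total_n
        found.append(best)
        covered |= matched_original
    return found


class MotifDiscovery:
    """Discover the prime motif (and mutually-exclusive motifs) of an RBP.

    sklearn-style estimator: ``fit(peak_sequences, null_corpus=...)``
    populates ``prime_motif_``, ``motifs_`` and ``seed_table_``.

    Parameters
    ----------
    seed_k : seed length (6).
    seed_radius : mismatches allowed at the seed stage (2).
    p_cutoff : binomial significance cutoff (0.01).
    min_coverage : fraction of peaks a prime motif must match (0.70).
    min_identity : mean per-instance identity kept during expansion (0.70).
    min_me_fraction : minimum original-data representation for a
        mutually-exclusive motif (0.20).
    max_expand : number of top significant seeds expanded.
    bonferroni : apply a 4^k multiple-testing correction to the seed
        p-values (off by default: the raw 0.01 cutoff is the reference
        behaviour).
    find_exclusive : also mine residual peaks for mutually-exclusive motifs.
    """

    def __init__(self, seed_k: int = DEFAULT_SEED_K, seed_radius: int = DEFAULT_SEED_RADIUS,
                 p_cutoff: float = 0.01, min_coverage: float = 0.70,
                 min_identity: float = 0.70, min_me_fraction: float = 0.20,
                 max_expand: int = 40, bonferroni: bool = False,
                 find_exclusive: bool = True):
        self.seed_k = seed_k
        self.seed_radius = seed_radius
        self.p_cutoff = p_cutoff
        self.min_coverage = min_coverage
        self.min_identity = min_identity
        self.min_me_fraction = min_me_fraction
        self.max_expand = max_expand
        self.bonferroni = bonferroni
        self.find_exclusive = find_exclusive

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "seed_k", "seed_radius", "p_cutoff", "min_coverage", "min_identity",
            "min_me_fraction", "max_expand", "bonferroni", "find_exclusive")}

    def set_params(self, **params) -> "MotifDiscovery":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[str], y=None, *, null_corpus: Sequence[str]):
        """Discover motifs in peak sequences ``X`` against ``null_corpus``."""
        peaks = [s.upper().replace("T", "U") for s in X]
        if not peaks:
            raise ValueError("empty peak set")
        if not null_corpus:
            raise ValueError("a null corpus is required")
        n = len(peaks)
        m = len(null_corpus)
        cutoff = self.p_cutoff / 4**self.seed_k if self.bonferroni else self.p_cutoff

        counts = seed_presence_counts(peaks, self.seed_k, self.seed_radius)
        null_counts = seed_presence_counts(null_corpus, self.seed_k, self.seed_radius)
        p0 = np.clip(null_counts / m, 1.0 / (2 * m), 1.0 - 1.0 / (2 * m))
        pvals = binomial_enrichment_pvalue(counts, n, p0)

        self.seed_pvalues_ = pvals
        self.seed_counts_ = counts
        self.null_p_ = p0

        enriched = pvals <= cutoff
        qualifying = enriched & (counts >= self.min_coverage * n)
        if qualifying.any():
            pool = qualifying
        elif enriched.any():
            # no seed reaches 70% of the data: take the highest representation
            pool = enriched & (counts == counts[enriched].max())
        else:
            raise ValueError("no significantly enriched seed found")
        order = np.lexsort((pvals[pool], -counts[pool]))
        cand_codes = np.nonzero(pool)[0][order][: self.max_expand]

        scanner = ConsensusScanner(peaks)
        self.seed_table_ = []
        candidates = []
        for code in cand_codes:
            seed = decode_kmer(int(code), self.seed_k)
            sr = KmerSeedResult(seed, self.seed_radius, int(counts[code]), n,
                                float(p0[code]), float(pvals[code]), True)
            self.seed_table_.append(sr)
            try:
                motif = expand_seed(sr, peaks, min_coverage=min(
                    self.min_coverage, sr.coverage), min_identity=self.min_identity,
                    scanner=scanner)
            except ValueError:
                continue
            candidates.append(motif)
        if not candidates:
            raise ValueError("no seed could be expanded")
        self.candidates_ = candidates
        self.prime_motif_ = select_prime(candidates)
        self.motifs_ = [self.prime_motif_]
        if self.find_exclusive:
            self.motifs_ += find_mutually_exclusive(
                peaks, self.prime_motif_.matched_peak_ids, null_corpus,
                min_fraction=self.min_me_fraction, p_cutoff=self.p_cutoff,
                min_identity=self.min_identity, max_expand=self.max_expand)
        return self


def write_motif_report(motifs: Sequence[PrimeMotif], tsv_path: str,
                       meme_path: Optional[str] = None) -> None:
    """TSV motif report plus optional MEME minimal-format PWMs."""
    with open(tsv_path, "w") as fh:
        fh.write("consensus\tlength\tcoverage\tpvalue\tkind\tmatched_peaks\n")
        for m in motifs:
            fh.write(f"{m.consensus}\t{len(m)}\t{m.coverage:.4f}\t"
                     f"{m.pvalue:.3e}\t{m.kind}\t{len(m.matched_peak_ids)}\n")
    if meme_path is None:
        return
    with open(meme_path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for m in motifs:
            freqs = m.frequencies
            nsites = max(int(m.pwm.sum(axis=0).max()), 1)
            fh.write(f"MOTIF {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)} "
                     f"nsites= {nsites} E= {m.pvalue:.2e}\n")
            for j in range(len(m)):
                fh.write(" ".join(f"{freqs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")
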