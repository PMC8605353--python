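"""Secondary motifs co-occurring with the prime motif in ±75-base flanks.

A candidate partner is called significant when four criteria hold
simultaneously: the anchor–partner distance distribution differs from
the random corpus (two-sample KS), the partner is over-represented among
anchor-bearing sequences (hypergeometric upper tail), the frequency
ratio FR exceeds 1, and the partner's PWM is dissimilar from the anchor
(shift-maximized Jaccard overlap < 0.2, so the "partner" is not the
anchor itself re-discovered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kmercode import hamming_ball_size
from .motifs import ConsensusScanner, PrimeMotif, mismatch_budget


def _as_consensus(motif) -> str:
    return motif.consensus if isinstance(motif, PrimeMotif) else str(motif)


@dataclass
class CooccurrenceStats:
    """Statistics for one anchor/partner motif pair."""

    anchor: str
    partner: str
    distances: list
    ks_stat: float
    ks_pvalue: float
    hyper_pvalue: float
    FR: float
    jaccard: float
    X: int  # sequences containing the anchor
    N: int  # ... of which also contain the partner
    Y: int  # sequences lacking the anchor
    M: int  # ... of which contain the partner
    ks_cutoff: float = 0.05

    @property
    def significant(self) -> bool:
        return (self.ks_pvalue < self.ks_cutoff and self.hyper_pvalue < 0.05
                and self.FR > 1.0 and self.jaccard < 0.2)


def distance_distribution(instances: Sequence[str], anchor_motif, candidate_motif,
                          window: int = 75, budget: Optional[int] = None
                          ) -> list[int]:
    """Signed offsets of the candidate's nearest hit relative to the
    anchor start, one per instance; instances without an anchor match or
    without a candidate hit inside ±window contribute nothing.

    ``budget`` is the candidate mismatch allowance (default: the 30%
    rule for its length; 0 gives exact matching). Ties on |offset|
    resolve to the upstream (negative) side.
    """
    anchor = _as_consensus(anchor_motif)
    cand = _as_consensus(candidate_motif)
    if len(cand) > 2 * window:
        raise ValueError("candidate longer than the co-occurrence window")
    if budget is None:
        budget = mismatch_budget(len(cand))
    scanner = ConsensusScanner(list(instances))
    a_matched, a_pos, _ = scanner.best_matches(anchor, mismatch_budget(len(anchor)))
    c_hits = scanner.all_matches(cand, budget)
    offsets: list[int] = []
    for i in range(scanner.n):
        if not a_matched[i] or i not in c_hits:
            continue
        rel = np.array(c_hits[i]) - int(a_pos[i])
        rel = rel[(rel >= -window) & (rel <= window)]
        rel = rel[rel != 0]  # the anchor position itself is not a co-occurrence
        if rel.size == 0:
            continue
        best = rel[np.lexsort((rel, np.abs(rel)))][0]
        offsets.append(int(best))
    return offsets


def ks_cooccurrence_test(observed_offsets: Sequence[float],
                         random_offsets: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test of the offset distributions."""
    if len(observed_offsets) == 0 or len(random_offsets) == 0:
        raise ValueError("both offset samples must be non-empty")
    if min(len(observed_offsets), len(random_offsets)) < 5:
        warnings.warn("KS sample smaller than 5; p-value is unstable",
                      stacklevel=2)
    res = stats.ks_2samp(observed_offsets, random_offsets)
    return float(res.statistic), float(res.pvalue)


def frequency_ratio(X: int, N: int, Y: int, M: int) -> float:
    """Conditional-rate ratio FR = (N/X) / (M/Y).

    FR > 1 means the partner occurs more often in anchor-bearing
    sequences than in anchor-free ones. N=0 gives 0; M=0 with N>0 is
    reported as +inf.
    """
    if X <= 0 or Y <= 0:
        raise ValueError("X and Y must be positive")
    if N == 0:
        return 0.0
    if M == 0:
        return float("inf")
    return (N / X) / (M / Y)


def hypergeometric_test(universe: int, with_m1: int, with_m2: int,
                        with_both: int) -> float:
    """Upper-tail P(overlap >= with_both) under hypergeom(universe, m1, m2)."""
    if not (0 <= with_both <= min(with_m1, with_m2) <= universe):
        raise ValueError("inconsistent counts")
    return float(stats.hypergeom.sf(with_both - 1, universe, with_m1, with_m2))


def pwm_jaccard(motifA, motifB, min_overlap: int = 4) -> float:
    """Shift-maximized Jaccard-style overlap of two PWMs, in [0, 1].

    For each relative shift with >= min_overlap aligned columns, aligned
    columns score sum(min)/sum(max) of the two frequency vectors and
    unaligned columns score 0; the per-shift value is the mean over the
    UNION of columns (la + lb - overlap), so a short chance overlap of
    long motifs cannot dominate. The maximum over shifts is returned.
    Symmetric by construction; identical PWMs score 1.
    """
    fa = motifA.frequencies if isinstance(motifA, PrimeMotif) else np.asarray(motifA, float)
    fb = motifB.frequencies if isinstance(motifB, PrimeMotif) else np.asarray(motifB, float)
    if fa.shape[0] != 4 or fb.shape[0] != 4:
        raise ValueError("PWMs must have 4 rows (A,C,G,U)")
    la, lb = fa.shape[1], fb.shape[1]
    best = 0.0
    for shift in range(-la + min_overlap, lb - min_overlap + 1):
        i0, j0 = max(0, -shift), max(0, shift)
        width = min(la - i0, lb - j0)
        if width < min_overlap:
            continue
        a = fa[:, i0 : i0 + width]
        b = fb[:, j0 : j0 + width]
        mins = np.minimum(a, b).sum(axis=0)
        maxs = np.maximum(a, b).sum(axis=0)
        with np.errstate(invalid="ignore"):
            ratio = np.where(maxs > 0, mins / np.maximum(maxs, 1e-300), 0.0)
        best = max(best, float(ratio.sum() / (la + lb - width)))
    return best


def model_word_jaccard(consA: str, consB: str, mA: Optional[int] = None,
                       mB: Optional[int] = None, min_overlap: int = 4) -> float:
    """Jaccard index of the word sets two mismatch-ball motif models
    recognize, maximized over relative shifts.

    A model (consensus, budget) recognizes a word when its window lies
    within the budget's Hamming distance of the consensus; positions
    outside a model's window are free. Identical models score 1; models
    whose balls share no word score 0 — so the <0.2 screen cleanly
    separates "same motif rediscovered" from a genuine partner.
    """
    if mA is None:
        mA = mismatch_budget(len(consA))
    if mB is None:
        mB = mismatch_budget(len(consB))
    kA, kB = len(consA), len(consB)
    best = 0.0
    for shift in range(-kA + min_overlap, kB - min_overlap + 1):
        overlap = min(kA, shift + kB) - max(0, shift)
        if overlap < min_overlap:
            continue
        start, end = min(0, shift), max(kA, shift + kB)
        # dp over (mismatches to A, mismatches to B), weighted by letter counts
        dp = np.zeros((mA + 2, mB + 2))
        dp[0, 0] = 1.0
        for p in range(start, end):
            in_a = 0 <= p < kA
            in_b = shift <= p < shift + kB
            a = consA[p] if in_a else None
            b = consB[p - shift] if in_b else None
            new = np.zeros_like(dp)
            if in_a and in_b:
                if a == b:
                    new[: mA + 1, : mB + 1] += dp[: mA + 1, : mB + 1]       # match both
                    new[1:, 1:] += 3 * dp[:-1, :-1]                          # miss both
                else:
                    new[: mA + 1, 1:] += dp[: mA + 1, :-1]                   # match A
                    new[1:, : mB + 1] += dp[:-1, : mB + 1]                   # match B
                    new[1:, 1:] += 2 * dp[:-1, :-1]                          # miss both
            elif in_a:
                new[: mA + 1, :] += dp[: mA + 1, :]
                new[1:, :] += 3 * dp[:-1, :]
            else:
                new[:, : mB + 1] += dp[:, : mB + 1]
                new[:, 1:] += 3 * dp[:, :-1]
            dp = new
        both = float(dp[: mA + 1, : mB + 1].sum())
        length = end - start
        only_a = hamming_ball_size(kA, mA) * 4.0 ** (length - kA)
        only_b = hamming_ball_size(kB, mB) * 4.0 ** (length - kB)
        denom = only_a + only_b - both
        if denom > 0:
            best = max(best, both / denom)
    return best


def _consensus_pwm(consensus: str) -> np.ndarray:
    from .kmercode import seq_to_codes

    codes = seq_to_codes(consensus)
    pwm = np.zeros((4, len(consensus)))
    for j, c in enumerate(codes):
        if c <= 3:
            pwm[c, j] = 1.0
    return pwm


def find_cooccurring(positive_instances: Sequence[str],
                     background_instances: Sequence[str],
                     anchor_motif, candidate_motifs: Sequence,
                     window: int = 75, ks_cutoff: float = 0.05
                     ) -> list[CooccurrenceStats]:
    """Evaluate candidate partners against the anchor.

    The KS test compares anchor–partner offsets in positives against
    offsets in the background instances. FR and the hypergeometric test
    partition the combined universe by instance class: X bound
    (positive, anchor in its bound context) vs Y background — negatives
    carry the anchor too by construction, so presence of the anchor
    string itself cannot partition the universe.
    """
    anchor = _as_consensus(anchor_motif)
    universe = list(positive_instances) + list(background_instances)
    scanner = ConsensusScanner(universe)
    n_pos = len(positive_instances)
    results = []
    for candidate in candidate_motifs:
        cand = _as_consensus(candidate)
        c_matched, _, _ = scanner.best_matches(cand, mismatch_budget(len(cand)))
        X = n_pos
        Y = len(universe) - n_pos
        N = int(c_matched[:n_pos].sum())
        M = int(c_matched[n_pos:].sum())
        obs = distance_distribution(positive_instances, anchor, cand, window)
        rnd = distance_distribution(background_instances, anchor, cand, window)
        if obs and rnd:
            ks_stat, ks_p = ks_cooccurrence_test(obs, rnd)
        else:
            ks_stat, ks_p = 0.0, 1.0
        hyper_p = hypergeometric_test(len(universe), X, N + M, N)
        fr = frequency_ratio(X, N, Y, M) if X > 0 and Y > 0 else 0.0
        results.append(CooccurrenceStats(
            anchor=anchor, partner=cand, distances=obs,
            ks_stat=ks_stat, ks_pvalue=ks_p, hyper_pvalue=hyper_p,
            FR=fr, jaccard=model_word_jaccard(anchor, cand),
            X=X, N=N, Y=Y, M=M, ks_cutoff=ks_cutoff))
    return results


def write_pair_report(pairs: Sequence[CooccurrenceStats], tsv_path: str,
                      histogram_path: Optional[str] = None,
                      window: int = 75) -> None:
    """Pair report TSV plus an optional per-pair offset histogram TSV."""
    with open(tsv_path, "w") as fh:
        fh.write("anchor\tpartner\tX\tN\tY\tM\tFR\tks_D\tks_p\thyper_p\t"
                 "jaccard\tsignificant\n")
        for p in pairs:
            fh.write(f"{p.anchor}\t{p.partner}\t{p.X}\t{p.N}\t{p.Y}\t{p.M}\t"
                     f"{p.FR:.4g}\t{p.ks_stat:.4f}\t{p.ks_pvalue:.3e}\t"
                     f"{p.hyper_pvalue:.3e}\t{p.jaccard:.4f}\t{p.significant}\n")
    if histogram_path is None:
        return
    with open(histogram_path, "w") as fh:
        fh.write("anchor\tpartner\toffset\tcount\n")
        for p in pairs:
            counts = np.bincount(np.array(p.distances) + window,
                                 minlength=2 * window + 1)
            for off in range(-window, window + 1):
                fh.write(f"{p.anchor}\t{p.partner}\t{off}\t{counts[off + window]}\n")
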