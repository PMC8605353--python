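"""Contextual feature vectors for anchored instances.

Three feature families describe the sequence context around the motif
anchor: positional dinucleotide densities in sliding windows (a proxy
for local structure/accessibility), and mismatch-tolerant pentamer and
heptamer positional probabilities projected from tensors estimated on
the training positives. Structure triplets from dot-bracket strings are
implemented but disabled in default model assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kmercode import BASES, hamming_ball_codes, seq_to_codes, window_codes

EPS = 1e-12
DINUCLEOTIDES = ["".join(p) for p in product(BASES, repeat=2)]
STRUCT_ALPHABET = ".()"
STRUCT_TRIPLETS = ["".join(p) for p in product(STRUCT_ALPHABET, repeat=3)]


def dinucleotide_window_densities(seq: str, window_size: int, step: int = 1
                                  ) -> np.ndarray:
    """Per-placement densities of the 16 dinucleotides.

    Returns an (n_placements, 16) array; density = count / (window-1),
    so each N-free placement's densities sum to 1. Placements containing
    N are NaN (imputed downstream from training means).
    """
    L = len(seq)
    if window_size > L:
        raise ValueError(f"window {window_size} larger than sequence ({L})")
    if window_size < 2:
        raise ValueError("window must span at least one dinucleotide")
    codes = seq_to_codes(seq)
    left, right = codes[:-1], codes[1:]
    valid = (left < 4) & (right < 4)
    dinuc = np.where(valid, left * 4 + right, 0)
    one_hot = np.zeros((L - 1, 16), dtype=np.int32)
    one_hot[np.arange(L - 1), dinuc] = valid
    cum = np.zeros((L, 16), dtype=np.int64)
    np.cumsum(one_hot, axis=0, out=cum[1:])
    cum_invalid = np.concatenate(([0], np.cumsum(~valid)))
    placements = np.arange(0, L - window_size + 1, step)
    span = window_size - 1
    dens = (cum[placements + span] - cum[placements]) / span
    bad = (cum_invalid[placements + span] - cum_invalid[placements]) > 0
    dens[bad] = np.nan
    return dens


@dataclass
class KmerTensor:
    """Per-position, per-k-mer probability table from training positives.

    probs[m, p] = fraction of training positives whose k-window at
    position p lies within Hamming distance <= mismatch_budget of k-mer m.
    """

    k: int
    mismatch_budget: int
    probs: np.ndarray       # (4^k, source_length - k + 1)
    n_source: int
    source_length: int

    @property
    def n_rows(self) -> int:
        return 4**self.k

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]


def build_kmer_tensor(training_positives: Sequence[str], k: int,
                      mismatch_budget: int = 2, chunk: int = 64) -> KmerTensor:
    """Estimate the k-mer positional probability tensor.

    For each sequence and position the Hamming ball of the observed
    k-mer is expanded (Hamming distance is symmetric), so a single pass
    over the training set fills every affected cell.
    """
    seqs = list(training_positives)
    if not seqs:
        raise ValueError("no training sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"unequal training sequence lengths: {sorted(lengths)}")
    L = lengths.pop()
    n_pos = L - k + 1
    if n_pos <= 0:
        raise ValueError("sequences shorter than k")
    n_rows = 4**k
    counts = np.zeros(n_rows * n_pos, dtype=np.int64)
    for start in range(0, len(seqs), chunk):
        flat_parts = []
        for seq in seqs[start : start + chunk]:
            codes = window_codes(seq, k)
            ok = codes >= 0
            if not ok.any():
                continue
            ball = hamming_ball_codes(codes[ok], k, mismatch_budget)
            pos = np.nonzero(ok)[0]
            flat_parts.append((ball * n_pos + pos[:, None]).ravel())
        if flat_parts:
            counts += np.bincount(np.concatenate(flat_parts),
                                  minlength=n_rows * n_pos)
    probs = counts.reshape(n_rows, n_pos) / len(seqs)
    return KmerTensor(k, mismatch_budget, probs, len(seqs), L)


def project_sequence(tensor: KmerTensor, seq: str) -> np.ndarray:
    """Positional probability vector: tensor cell of the k-mer observed
    at each position. Positions whose window contains N project to 0."""
    if len(seq) != tensor.source_length:
        raise ValueError(
            f"sequence length {len(seq)} != tensor source length "
            f"{tensor.source_length}")
    codes = window_codes(seq, tensor.k)
    out = np.zeros(tensor.n_positions)
    ok = codes >= 0
    out[ok] = tensor.probs[codes[ok], np.nonzero(ok)[0]]
    return out


def structure_triplet_densities(dotbracket: str, window: Optional[int] = None
                                ) -> np.ndarray:
    """Densities of the 27 structure triplets over {., (, )}.

    ``window`` restricts the computation to the centered window of that
    size; default is the whole string.
    """
    bad = set(dotbracket) - set(STRUCT_ALPHABET)
    if bad:
        raise ValueError(f"illegal dot-bracket characters: {sorted(bad)}")
    if window is not None:
        if window > len(dotbracket):
            raise ValueError("window larger than structure string")
        start = (len(dotbracket) - window) // 2
        dotbracket = dotbracket[start : start + window]
    n = len(dotbracket) - 2
    if n <= 0:
        raise ValueError("structure string shorter than a triplet")
    idx = {c: i for i, c in enumerate(STRUCT_ALPHABET)}
    dens = np.zeros(27)
    for i in range(n):
        a, b, c = dotbracket[i : i + 3]
        dens[idx[a] * 9 + idx[b] * 3 + idx[c]] += 1
    return dens / n


@dataclass
class FeatureStats:
    """Per-feature discrimination statistics, ordered by F-score."""

    fscores: np.ndarray
    t_pvalues: np.ndarray
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    mean_all: np.ndarray
    n_pos: int
    n_neg: int
    ranking: np.ndarray  # feature indices, descending F, stable ties


def fscore_rank(matrix: np.ndarray, labels: np.ndarray) -> FeatureStats:
    """F-score of every feature: squared deviations of the class means
    from the global mean over the summed within-class sample variances
    (n-1 denominators), with a small epsilon guarding zero variance.

        F(i) = [(x̄i⁺ − x̄i)² + (x̄i⁻ − x̄i)²] / [s²i⁺ + s²i⁻ + ε]

    Also reports a two-sample t-test p-value per feature.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >=2 instances for sample variances")
    mean_pos, mean_neg, mean_all = pos.mean(0), neg.mean(0), X.mean(0)
    var_pos = pos.var(0, ddof=1)
    var_neg = neg.var(0, ddof=1)
    fscores = ((mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2) / (
        var_pos + var_neg + EPS)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        t_pvalues = stats.ttest_ind(pos, neg, axis=0).pvalue
    t_pvalues = np.where(np.isnan(t_pvalues), 1.0, t_pvalues)
    ranking = np.argsort(-fscores, kind="stable")
    return FeatureStats(fscores, t_pvalues, mean_pos, mean_neg, mean_all,
                        len(pos), len(neg), ranking)


class ContextFeaturizer:
    """Convert anchored instances into contextual feature vectors.

    sklearn-style transformer: ``fit(train_sequences, train_labels)``
    estimates the pentamer/heptamer tensors from the TRAINING POSITIVES
    only and the dinucleotide imputation means from all training
    instances; ``transform`` featurizes any same-length sequences with
    the frozen schema.

    Parameters
    ----------
    window_size : dinucleotide sliding-window size (odd, 17..131).
    use_dinucleotide, use_pentamer, use_heptamer : enabled blocks.
    use_structure : append 27 structure-triplet densities (requires
        dot-bracket strings at transform time; off by default).
    mismatch_budget : Hamming tolerance of the k-mer tensors (2).
    strict_columns : drop the last tensor column, reproducing an (L-k)
        position count instead of the standard L-k+1.
    """

    def __init__(self, window_size: int = 43, use_dinucleotide: bool = True,
                 use_pentamer: bool = True, use_heptamer: bool = True,
                 use_structure: bool = False, mismatch_budget: int = 2,
                 strict_columns: bool = False):
        self.window_size = window_size
        self.use_dinucleotide = use_dinucleotide
        self.use_pentamer = use_pentamer
        self.use_heptamer = use_heptamer
        self.use_structure = use_structure
        self.mismatch_budget = mismatch_budget
        self.strict_columns = strict_columns

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "window_size", "use_dinucleotide", "use_pentamer", "use_heptamer",
            "use_structure", "mismatch_budget", "strict_columns")}

    def set_params(self, **params) -> "ContextFeaturizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _tensor_cols(self, k: int) -> int:
        cols = self.sequence_length_ - k + 1
        return cols - 1 if self.strict_columns else cols

    def fit(self, X: Sequence[str], y=None) -> "ContextFeaturizer":
        seqs = list(X)
        if not seqs:
            raise ValueError("no training sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("training sequences must share one length")
        self.sequence_length_ = lengths.pop()
        if y is None:
            positives = seqs
        else:
            y = np.asarray(y).astype(int)
            positives = [s for s, lab in zip(seqs, y) if lab == 1]
            if not positives:
                raise ValueError("no positive training sequences for the tensors")
        self.tensors_ = {}
        if self.use_pentamer:
            self.tensors_[5] = build_kmer_tensor(positives, 5, self.mismatch_budget)
        if self.use_heptamer:
            self.tensors_[7] = build_kmer_tensor(positives, 7, self.mismatch_budget)
        names = []
        if self.use_dinucleotide:
            n_place = self.sequence_length_ - self.window_size + 1
            names += [f"dinuc_w{self.window_size}_p{p}_{d}"
                      for p in range(n_place) for d in DINUCLEOTIDES]
            raw = np.vstack([
                dinucleotide_window_densities(s, self.window_size).ravel()
                for s in seqs])
            col_mean = np.nanmean(raw, axis=0)
            self.dinuc_impute_ = np.where(np.isnan(col_mean), 0.0, col_mean)
        if self.use_pentamer:
            names += [f"pentamer_p{p}" for p in range(self._tensor_cols(5))]
        if self.use_heptamer:
            names += [f"heptamer_p{p}" for p in range(self._tensor_cols(7))]
        if self.use_structure:
            names += [f"struct_{t}" for t in STRUCT_TRIPLETS]
        self.feature_names_ = names
        self.n_features_ = len(names)
        return self

    def transform(self, X: Sequence[str],
                  structures: Optional[Sequence[str]] = None) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("featurizer is not fitted")
        seqs = list(X)
        for s in seqs:
            if len(s) != self.sequence_length_:
                raise ValueError(
                    f"sequence length {len(s)} != fitted length "
                    f"{self.sequence_length_}")
        blocks = []
        if self.use_dinucleotide:
            raw = np.vstack([
                dinucleotide_window_densities(s, self.window_size).ravel()
                for s in seqs])
            nan_mask = np.isnan(raw)
            if nan_mask.any():
                raw[nan_mask] = np.broadcast_to(self.dinuc_impute_, raw.shape)[nan_mask]
            blocks.append(raw)
        for k in (5, 7):
            if k in self.tensors_:
                proj = np.vstack([project_sequence(self.tensors_[k], s) for s in seqs])
                blocks.append(proj[:, : self._tensor_cols(k)])
        if self.use_structure:
            if structures is None:
                raise ValueError("structure block enabled but no dot-bracket "
                                 "strings supplied")
            blocks.append(np.vstack([
                structure_triplet_densities(db) for db in structures]))
        out = np.hstack(blocks)
        assert out.shape[1] == self.n_features_
        return out

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, y).transform(X, **kw)
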