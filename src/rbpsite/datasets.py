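"""Peak filtering and balanced positive/negative instance construction.

An instance is the prime-motif anchor plus 75 flanking bases on each
side, so instances are motif_length + 150 long (156 for a 6-mer anchor,
160 for a 10-mer). Negatives carry the same motif in an unbound context:
Set A draws them from expressed-but-unbound transcripts, Set B from
distal motif occurrences on bound transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import PeakInterval, SequenceRecord, extract_sequence
from .motifs import ConsensusScanner, PrimeMotif, mismatch_budget

MIN_PEAK_LEN = 5
MAX_PEAK_LEN = 300
ELIGIBILITY_MIN_PEAKS = 500
DEFAULT_FLANK = 75


@dataclass
class Instance:
    """One fixed-length anchored sequence with provenance."""

    sequence: str
    origin: str
    label: int            # 1 = bound (positive), 0 = unbound
    strategy: str = ""    # "", "A" or "B" for negatives


@dataclass
class InstanceSet:
    """Labeled, balanced, split instance collection for one RBP."""

    rbp_id: str
    motif_length: int
    instances: list
    train_mask: np.ndarray
    rng_seed: int

    @property
    def instance_length(self) -> int:
        return self.motif_length + 2 * DEFAULT_FLANK

    @property
    def sequences(self) -> list[str]:
        return [i.sequence for i in self.instances]

    @property
    def labels(self) -> np.ndarray:
        return np.array([i.label for i in self.instances], dtype=int)

    def _part(self, train: bool):
        mask = self.train_mask if train else ~self.train_mask
        idx = np.nonzero(mask)[0]
        return [self.instances[i].sequence for i in idx], self.labels[idx]

    @property
    def train(self):
        return self._part(True)

    @property
    def test(self):
        return self._part(False)


def filter_peaks(peaks: Sequence[PeakInterval]) -> list[PeakInterval]:
    """Keep peaks of length 5..300 (inclusive); collapse duplicates
    (identical coordinates + strand), preserving first occurrence."""
    seen = set()
    kept = []
    for p in peaks:
        if not MIN_PEAK_LEN <= len(p) <= MAX_PEAK_LEN:
            continue
        if p.key in seen:
            continue
        seen.add(p.key)
        kept.append(p)
    return kept


def check_rbp_eligibility(peaks: Sequence[PeakInterval]) -> bool:
    """An RBP qualifies only with more than 500 unique peaks."""
    return len(peaks) > ELIGIBILITY_MIN_PEAKS


def _motif_positions(sequence: str, motif: PrimeMotif) -> list[int]:
    scanner = ConsensusScanner([sequence])
    hits = scanner.all_matches(motif.consensus, mismatch_budget(len(motif)))
    return hits.get(0, [])


def build_positive(peaks: Sequence[PeakInterval], genome: Mapping,
                   prime_motif: PrimeMotif, flank: int = DEFAULT_FLANK
                   ) -> list[Instance]:
    """One instance per prime-motif occurrence inside a peak, expanded by
    ±flank bases taken from the source sequence (not just the peak).

    Occurrences whose flanks would run off the source sequence are
    skipped so that every instance has identical length.
    """
    k = len(prime_motif)
    out: list[Instance] = []
    for peak in peaks:
        seq = peak.sequence if peak.sequence is not None else extract_sequence(genome, peak)
        for pos in _motif_positions(seq, prime_motif):
            if peak.strand == "+":
                m_start = peak.start + pos
                m_end = m_start + k
            else:  # position counted from the 3' end of the forward interval
                m_end = peak.end - pos
                m_start = m_end - k
            ext_start, ext_end = m_start - flank, m_end + flank
            if ext_start < 0 or ext_end > len(genome[peak.chrom]):
                continue
            ext = PeakInterval(peak.chrom, ext_start, ext_end, peak.strand)
            out.append(Instance(
                sequence=extract_sequence(genome, ext),
                origin=f"{peak.chrom}:{ext_start}-{ext_end}({peak.strand})",
                label=1))
    if not out:
        raise ValueError("prime motif not found in any peak")
    return out


def build_negative_setA(unbound_transcripts: Sequence[SequenceRecord],
                        prime_motif: PrimeMotif,
                        bound_transcript_ids: Optional[set] = None,
                        flank: int = DEFAULT_FLANK) -> list[Instance]:
    """Motif-anchored instances from transcripts that are expressed in
    the same condition but never appear in the peak data (Set A)."""
    bound = bound_transcript_ids or set()
    k = len(prime_motif)
    out: list[Instance] = []
    for rec in unbound_transcripts:
        if rec.id in bound:
            continue
        for pos in _motif_positions(rec.sequence, prime_motif):
            s, e = pos - flank, pos + k + flank
            if s < 0 or e > len(rec.sequence):
                continue
            out.append(Instance(rec.sequence[s:e], f"{rec.id}:{s}-{e}", 0, "A"))
    return out


def build_negative_setB(transcripts: Mapping[str, str],
                        peak_intervals: Sequence[PeakInterval],
                        prime_motif: PrimeMotif,
                        flank: int = DEFAULT_FLANK,
                        min_distance: int = 300) -> list[Instance]:
    """Motif occurrences on bound transcripts that lie at least
    ``min_distance`` bases from every peak on that transcript (Set B).

    ``peak_intervals`` must be expressed in the transcripts' coordinates
    (chrom = transcript id).
    """
    k = len(prime_motif)
    by_transcript: dict[str, list[PeakInterval]] = {}
    for p in peak_intervals:
        by_transcript.setdefault(p.chrom, []).append(p)
    out: list[Instance] = []
    for tid, peaks in by_transcript.items():
        if tid not in transcripts:
            continue
        seq = transcripts[tid]
        for pos in _motif_positions(seq, prime_motif):
            m_start, m_end = pos, pos + k
            far_enough = all(
                m_start - p.end >= min_distance or p.start - m_end >= min_distance
                for p in peaks)
            if not far_enough:
                continue
            s, e = m_start - flank, m_end + flank
            if s < 0 or e > len(seq):
                continue
            out.append(Instance(seq[s:e], f"{tid}:{s}-{e}", 0, "B"))
    return out


def balance_and_split(positives: Sequence[Instance], negatives: Sequence[Instance],
                      train_fraction: float = 0.7, rng_seed: int = 0,
                      rbp_id: str = "rbp", motif_length: Optional[int] = None,
                      min_per_class: int = 50) -> InstanceSet:
    """Downsample the larger class to equality, then make a stratified,
    leakage-free train/test split.

    A sequence string appearing in both classes is dropped from both
    with a warning; the split is deterministic under ``rng_seed`` and no
    sequence string crosses the partition boundary.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    pos_seqs = {i.sequence for i in positives}
    neg_seqs = {i.sequence for i in negatives}
    shared = pos_seqs & neg_seqs
    if shared:
        warnings.warn(f"{len(shared)} sequences occur in both classes; dropped",
                      stacklevel=2)
        positives = [i for i in positives if i.sequence not in shared]
        negatives = [i for i in negatives if i.sequence not in shared]
    lengths = {len(i.sequence) for i in list(positives) + list(negatives)}
    if len(lengths) > 1:
        raise ValueError(f"instances have unequal lengths: {sorted(lengths)}")

    rng = np.random.default_rng(rng_seed)
    n = min(len(positives), len(negatives))
    if n < min_per_class:
        raise ValueError(f"only {n} instances per class after balancing; "
                         f"minimum is {min_per_class}")

    def sample(pool):
        idx = rng.permutation(len(pool))[:n]
        return [pool[i] for i in sorted(idx)]

    positives, negatives = sample(list(positives)), sample(list(negatives))
    instances = list(positives) + list(negatives)

    # split at the level of distinct sequence strings so duplicates never
    # straddle the partition
    train_mask = np.zeros(len(instances), dtype=bool)
    for cls_instances, offset in ((positives, 0), (negatives, n)):
        uniq = sorted({i.sequence for i in cls_instances})
        order = rng.permutation(len(uniq))
        n_train = int(round(train_fraction * len(uniq)))
        train_seqs = {uniq[i] for i in order[:n_train]}
        for j, inst in enumerate(cls_instances):
            train_mask[offset + j] = inst.sequence in train_seqs

    if motif_length is None:
        length = len(instances[0].sequence)
        motif_length = length - 2 * DEFAULT_FLANK
    return InstanceSet(rbp_id, motif_length, instances, train_mask, rng_seed)


def write_instance_set(iset: InstanceSet, fasta_path: str, manifest_path: str) -> None:
    """Serialize as FASTA (id encodes label/strategy/split) + TSV manifest."""
    from .io import write_fasta

    records, rows = [], []
    for idx, inst in enumerate(iset.instances):
        split = "train" if iset.train_mask[idx] else "test"
        label = "pos" if inst.label else f"neg{inst.strategy}"
        rid = f"{iset.rbp_id}|{idx}|{label}|{split}"
        records.append(SequenceRecord(rid, inst.sequence))
        rows.append((rid, inst.origin, inst.label, inst.strategy, split))
    write_fasta(records, fasta_path)
    with open(manifest_path, "w") as fh:
        fh.write("id\torigin\tlabel\tstrategy\tsplit\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
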