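"""End-user prediction: scan sequences for classified binding sites.

A trained model container bundles the prime motif, the fitted context
featurizer (with its tensors and schema) and the classifier. Scanning
locates motif anchors within the mismatch budget, featurizes the ±75
base context of each occurrence, scores it and reports calls above the
threshold. '-' strand calls are reported in forward-reference
coordinates with strand '-' (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import joblib

from .datasets import DEFAULT_FLANK
from .features import ContextFeaturizer
from .io import SequenceRecord, normalize_rna, reverse_complement
from .models import BindingSiteClassifier
from .motifs import ConsensusScanner, PrimeMotif, mismatch_budget

MODEL_FORMAT_VERSION = 1


@dataclass
class BindingSiteCall:
    """One predicted binding site (anchor coordinates are 0-based
    half-open on the forward reference)."""

    sequence_id: str
    strand: str
    start: int
    end: int
    motif: str
    mismatches: int
    score: float
    verdict: bool


def save_model(path: str, prime_motif: PrimeMotif,
               featurizer: ContextFeaturizer,
               classifier: BindingSiteClassifier,
               threshold: float = 0.5, config: Optional[dict] = None) -> None:
    """Persist a versioned model container embedding the feature schema."""
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "prime_motif": prime_motif,
        "featurizer": featurizer,
        "classifier": classifier,
        "threshold": threshold,
        "config": config or {},
    }, path)


def load_model(path: str) -> dict:
    container = joblib.load(path)
    if container.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model container version")
    return container


def _scan_one_strand(model: dict, sid: str, seq: str, strand: str,
                     threshold: float, flank: int) -> list[BindingSiteCall]:
    motif: PrimeMotif = model["prime_motif"]
    featurizer: ContextFeaturizer = model["featurizer"]
    k = len(motif)
    budget = mismatch_budget(k)
    scanner = ConsensusScanner([seq])
    hits = scanner.all_matches(motif.consensus, budget).get(0, [])
    anchors, instances, mms = [], [], []
    for pos in hits:
        s, e = pos - flank, pos + k + flank
        if s < 0 or e > len(seq):
            continue  # edge occurrence: insufficient flank
        window = seq[pos : pos + k]
        mm = sum(a != b for a, b in zip(window, motif.consensus))
        anchors.append(pos)
        instances.append(seq[s:e])
        mms.append(mm)
    if not instances:
        return []
    scores = model["classifier"].decision_scores(featurizer.transform(instances))
    calls = []
    L = len(seq)
    for pos, mm, score in zip(anchors, mms, scores):
        if strand == "+":
            start, end = pos, pos + k
        else:
            start, end = L - (pos + k), L - pos
        calls.append(BindingSiteCall(sid, strand, start, end, motif.consensus,
                                     mm, float(score), bool(score >= threshold)))
    return calls


def scan(model: Union[str, dict], sequences: Sequence[SequenceRecord],
         strand_mode: str = "sense", threshold: Optional[float] = None,
         flank: int = DEFAULT_FLANK, keep_below_threshold: bool = False
         ) -> list[BindingSiteCall]:
    """Scan sequences for binding sites with a trained model.

    ``strand_mode`` is one of 'sense', 'antisense' or 'both'. Sequences
    shorter than the model's instance length are skipped with a warning.
    Deterministic for a fixed model and input.
    """
    if strand_mode not in ("sense", "antisense", "both"):
        raise ValueError("strand_mode must be sense, antisense or both")
    if isinstance(model, str):
        model = load_model(model)
    if threshold is None:
        threshold = model["threshold"]
    instance_length = model["featurizer"].sequence_length_
    strands = {"sense": ["+"], "antisense": ["-"], "both": ["+", "-"]}[strand_mode]
    calls: list[BindingSiteCall] = []
    for rec in sequences:
        seq = normalize_rna(rec.sequence)
        if len(seq) < instance_length:
            warnings.warn(f"{rec.id}: shorter than the instance length "
                          f"({instance_length}); skipped", stacklevel=2)
            continue
        for strand in strands:
            s = seq if strand == "+" else reverse_complement(seq)
            calls.extend(_scan_one_strand(model, rec.id, s, strand,
                                          threshold, flank))
    if not keep_below_threshold:
        calls = [c for c in calls if c.verdict]
    return sorted(calls, key=lambda c: (c.sequence_id, c.start, c.strand))


def merge_overlapping(calls: Sequence[BindingSiteCall],
                      min_overlap_fraction: float = 0.5
                      ) -> list[BindingSiteCall]:
    """Collapse same-strand calls overlapping by >= the given fraction
    of the shorter anchor, keeping the best-scoring one."""
    kept: list[BindingSiteCall] = []
    for call in sorted(calls, key=lambda c: (c.sequence_id, c.strand, -c.score)):
        clash = False
        for other in kept:
            if other.sequence_id != call.sequence_id or other.strand != call.strand:
                continue
            ov = min(call.end, other.end) - max(call.start, other.start)
            shorter = min(call.end - call.start, other.end - other.start)
            if ov > 0 and ov / shorter >= min_overlap_fraction:
                clash = True
                break
        if not clash:
            kept.append(call)
    return sorted(kept, key=lambda c: (c.sequence_id, c.start, c.strand))


def report_calls(calls: Sequence[BindingSiteCall], bed_path: str,
                 tsv_path: str) -> None:
    """BED6 (score column = round(1000 * classifier score)) + full TSV."""
    with open(bed_path, "w") as fh:
        for c in calls:
            fh.write(f"{c.sequence_id}\t{c.start}\t{c.end}\t{c.motif}\t"
                     f"{round(1000 * c.score)}\t{c.strand}\n")
    with open(tsv_path, "w") as fh:
        fh.write("sequence_id\tstrand\tstart\tend\tmotif\tmismatches\t"
                 "score\tverdict\n")
        for c in calls:
            fh.write(f"{c.sequence_id}\t{c.strand}\t{c.start}\t{c.end}\t"
                     f"{c.motif}\t{c.mismatches}\t{c.score:.6f}\t{c.verdict}\n")
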