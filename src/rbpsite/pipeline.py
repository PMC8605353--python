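"""End-to-end convenience drivers gluing the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datasets import balance_and_split, build_negative_setA, build_positive, filter_peaks
from .features import ContextFeaturizer

from .models import BindingSiteClassifier, evaluate
from .motifs import MotifDiscovery
from .simulate import SimulationConfig, null_corpus, simulate_background, simulate_peakset


@dataclass
class BenchmarkResult:
    """Outcome of one synthetic end-to-end run."""

    prime_consensus: str
    coverage: float
    metrics: dict
    ablated_metrics: Optional[dict] = None
    instance_set: object = None
    model: object = None
    featurizer: object = None
    prime_motif: object = None


def _extract_peak_sequences(transcripts, peaks):
    return [transcripts[p.chrom][p.start : p.end] for p in peaks]


def run_synthetic_benchmark(config: SimulationConfig,
                            model_kind: str = "gbt",
                            n_estimators: int = 300,
                            window_size: int = 43,
                            train_fraction: float = 0.7,
                            min_per_class: int = 50,
                            ablate_anchor: bool = False,
                            rng_seed: Optional[int] = None) -> BenchmarkResult:
    """Simulate, discover the prime motif, build Set-A datasets, featurize,
    train and evaluate on the held-out split.

    With ``ablate_anchor`` instances are extracted at RANDOM positions
    instead of prime-motif anchors (the anchor-ablation control): the
    features lose their alignment to the bound site.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    transcripts, peaks, truth = simulate_peakset(config)
    peaks = filter_peaks(peaks)
    peak_seqs = _extract_peak_sequences(transcripts, peaks)
    null = null_corpus(config, [len(s) for s in peak_seqs])

    disc = MotifDiscovery(find_exclusive=False)
    disc.fit(peak_seqs, null_corpus=null)
    prime = disc.prime_motif_

    pools = simulate_background(config)
    if ablate_anchor:
        rng = np.random.default_rng(seed + 7)
        positives = _random_anchor_instances(
            [(p.chrom, transcripts[p.chrom], p.start, p.end) for p in peaks],
            len(prime), rng, label=1)
        negatives = _random_anchor_instances(
            [(r.id, r.sequence, 0, len(r.sequence)) for r in pools.set_a],
            len(prime), rng, label=0)
    else:
        positives = build_positive(peaks, transcripts, prime)
        negatives = build_negative_setA(pools.set_a, prime)
    iset = balance_and_split(positives, negatives, train_fraction=train_fraction,
                             rng_seed=seed, min_per_class=min_per_class)

    train_seqs, train_labels = iset.train
    test_seqs, test_labels = iset.test

    featurizer = ContextFeaturizer(window_size=window_size)
    featurizer.fit(train_seqs, train_labels)
    X_train = featurizer.transform(train_seqs)
    X_test = featurizer.transform(test_seqs)

    model = BindingSiteClassifier(kind=model_kind, n_estimators=n_estimators,
                                  random_state=seed)
    model.fit(X_train, train_labels)
    _, metrics = evaluate(model, X_test, test_labels)
    return BenchmarkResult(prime.consensus, prime.coverage, metrics,
                           instance_set=iset, model=model,
                           featurizer=featurizer, prime_motif=prime)


def _random_anchor_instances(regions, k: int, rng, label: int, flank: int = 75):
    """Instances anchored at a random position of each region instead of
    a motif occurrence (anchor-ablation control)."""
    from .datasets import Instance

    out = []
    for rid, seq, lo, hi in regions:
        lo = max(lo, flank)
        hi = min(hi, len(seq) - k - flank)
        if hi < lo:
            continue
        pos = int(rng.integers(lo, hi + 1))
        out.append(Instance(seq[pos - flank : pos + k + flank],
                            f"{rid}:{pos}", label, "ablated"))
    return out
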