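import numpy as np
import pytest

from rbpsite.simulate import SimulationConfig, null_corpus, simulate_peakset


@pytest.fixture(scope="session")
def planted_corpus():
    """One reference planted-motif corpus shared across tests.

    500 peaks, 8-mer consensus UGCAUGCC at 80% coverage, 5% per-base
    substitution noise, uniform background.
    """
    cfg = SimulationConfig(rng_seed=2024)
    transcripts, peaks, truth = simulate_peakset(cfg)
    peak_seqs = [transcripts[p.chrom][p.start : p.end] for p in peaks]
    null = null_corpus(cfg, [len(s) for s in peak_seqs])
    return {"config": cfg, "transcripts": transcripts, "peaks": peaks,
            "truth": truth, "peak_seqs": peak_seqs, "null": null}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
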