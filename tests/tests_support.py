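"""Shared helpers for the test suite."""

import numpy as np

from rbpsite.motifs import PrimeMotif

_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}


def prime_from_consensus(consensus, coverage=1.0):
    """One-hot PrimeMotif wrapper around a consensus string."""
    pwm = np.zeros((4, len(consensus)))
    for j, ch in enumerate(consensus):
        pwm[_IDX[ch], j] = 1.0
    return PrimeMotif(consensus, pwm, coverage, set())
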