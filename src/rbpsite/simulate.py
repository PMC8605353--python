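"""Synthetic CLIP-seq-like corpora with controllable planted signal.

Every generator is a pure function of its configuration (including the
RNG seed), so fixtures are reproducible byte-for-byte. The generator
emulates the statistical structure the discovery method assumes: a
consensus motif carried by a controlled fraction of peaks with per-base
substitution noise, optional CG-enriched flanks around bound sites, an
optional secondary motif at a preferred offset, and background pools
for Set A / Set B negative construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import PeakInterval, SequenceRecord

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults are the reference planted-motif benchmark: 500 peaks, an
    8-mer consensus carried by 80% of peaks with 5% per-base
    substitution noise, uniform background, neutral flanks and no
    secondary motif.
    """

    n_peaks: int = 500
    peak_len_range: tuple = (50, 150)
    background_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    motif: str = "UGCAUGCC"
    coverage: float = 0.8
    substitution_rate: float = 0.05
    flank_cg_factor: float = 1.0
    flank: int = 75
    margin: int = 200
    secondary_motif: Optional[str] = None
    secondary_offset_mean: int = -30
    secondary_offset_jitter: int = 2
    secondary_carriage: float = 0.6
    background_secondary_rate: float = 0.05
    n_background: int = 300
    setb_distal_distance: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.coverage, self.substitution_rate,
                     self.secondary_carriage, self.background_secondary_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 6 <= len(self.motif) <= 10:
            raise ValueError("motif length must be 6..10")
        if len(self.motif) > self.peak_len_range[0]:
            raise ValueError("motif longer than the shortest peak")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, salt])


def _sample_bases(rng, length: int, freqs) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(freqs, dtype=float))


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _noised_motif(rng, motif: str, rate: float) -> tuple[str, int]:
    codes = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in motif])
    flips = rng.random(len(codes)) < rate
    shifted = (codes + rng.integers(1, 4, size=len(codes))) % 4
    out = np.where(flips, shifted, codes)
    return _to_str(out), int(flips.sum())


def _biased_flank(rng, length: int, base_freqs, cg_factor: float,
                  tolerance: float = 0.05, max_tries: int = 50) -> np.ndarray:
    """Flank with C+G content boosted by ``cg_factor``; rejection-sampled
    until the realized CG density is within ``tolerance`` of target."""
    p = np.asarray(base_freqs, dtype=float).copy()
    target = min(0.9, (p[1] + p[2]) * cg_factor)
    p[[1, 2]] *= target / (p[1] + p[2])
    p[[0, 3]] *= (1.0 - target) / (p[0] + p[3])
    p /= p.sum()
    best, best_err = None, np.inf
    for _ in range(max_tries):
        codes = _sample_bases(rng, length, p)
        cg = np.isin(codes, (1, 2)).mean()
        err = abs(cg - target)
        if err < best_err:
            best, best_err = codes, err
        if err <= tolerance:
            break
    return best


def simulate_peakset(config: SimulationConfig
                     ) -> tuple[dict, list[PeakInterval], pd.DataFrame]:
    """Generate bound transcripts, their peak intervals and a truth table.

    Exactly round(coverage * n_peaks) peaks carry the (noised) motif.
    Each peak sits on its own transcript with ``margin`` bases of source
    sequence on each side so that ±flank instance extraction never runs
    off the sequence. The truth table records every planted motif
    position (transcript coordinates), its mismatch count and any
    secondary-motif placement.
    """
    rng = _rng(config, 1)
    k = len(config.motif)
    n_carriers = int(round(config.coverage * config.n_peaks))
    carrier = np.zeros(config.n_peaks, dtype=bool)
    carrier[rng.choice(config.n_peaks, size=n_carriers, replace=False)] = True

    transcripts: dict[str, str] = {}
    peaks: list[PeakInterval] = []
    rows = []
    lo, hi = config.peak_len_range
    for i in range(config.n_peaks):
        tid = f"tx{i:05d}"
        peak_len = int(rng.integers(lo, hi + 1))
        tlen = peak_len + 2 * config.margin
        codes = _sample_bases(rng, tlen, config.background_freqs)
        motif_start = -1
        mismatches = 0
        partner_offset = None
        if carrier[i]:
            pos = int(rng.integers(0, peak_len - k + 1))
            motif_start = config.margin + pos
            planted, mismatches = _noised_motif(rng, config.motif,
                                                config.substitution_rate)
            codes[motif_start : motif_start + k] = [
                {"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in planted]
            if config.flank_cg_factor != 1.0:
                left = _biased_flank(rng, config.flank, config.background_freqs,
                                     config.flank_cg_factor)
                right = _biased_flank(rng, config.flank, config.background_freqs,
                                      config.flank_cg_factor)
                codes[motif_start - config.flank : motif_start] = left
                codes[motif_start + k : motif_start + k + config.flank] = right
            if (config.secondary_motif is not None
                    and rng.random() < config.secondary_carriage):
                jit = int(rng.integers(-config.secondary_offset_jitter,
                                       config.secondary_offset_jitter + 1))
                partner_offset = config.secondary_offset_mean + jit
                p_start = motif_start + partner_offset
                p_codes = [{"A": 0, "C": 1, "G": 2, "U": 3}[c]
                           for c in config.secondary_motif]
                if 0 <= p_start and p_start + len(p_codes) <= tlen:
                    codes[p_start : p_start + len(p_codes)] = p_codes
                else:
                    partner_offset = None
        transcripts[tid] = _to_str(codes)
        peaks.append(PeakInterval(tid, config.margin, config.margin + peak_len, "+"))
        rows.append({"peak_id": i, "transcript": tid, "has_motif": bool(carrier[i]),
                     "motif_start": motif_start, "mismatches": mismatches,
                     "partner_offset": partner_offset})
    return transcripts, peaks, pd.DataFrame(rows)


@dataclass
class BackgroundPools:
    """Negative-construction material: Set A unbound transcripts and
    Set B bound transcripts with a distal motif occurrence."""

    set_a: list
    set_a_truth: pd.DataFrame
    set_b_transcripts: dict
    set_b_peaks: list
    set_b_truth: pd.DataFrame


def simulate_background(config: SimulationConfig) -> BackgroundPools:
    """Unbound motif-bearing transcripts (Set A) and bound transcripts
    with a distal motif at a recorded distance (Set B)."""
    rng = _rng(config, 2)
    k = len(config.motif)
    code_of = {"A": 0, "C": 1, "G": 2, "U": 3}

    set_a, rows_a = [], []
    for i in range(config.n_background):
        tlen = int(rng.integers(400, 601))
        codes = _sample_bases(rng, tlen, config.background_freqs)
        pos = int(rng.integers(config.flank, tlen - k - config.flank + 1))
        planted, mism = _noised_motif(rng, config.motif, config.substitution_rate)
        codes[pos : pos + k] = [code_of[c] for c in planted]
        partner_offset = None
        if (config.secondary_motif is not None
                and rng.random() < config.background_secondary_rate):
            m2 = len(config.secondary_motif)
            while True:
                off = int(rng.integers(-config.flank, config.flank - m2 + 1))
                if off + m2 <= 0 or off >= k:  # keep the anchor intact
                    break
            p_start = pos + off
            if 0 <= p_start and p_start + m2 <= tlen:
                codes[p_start : p_start + m2] = [code_of[c]
                                                 for c in config.secondary_motif]
                partner_offset = off
        set_a.append(SequenceRecord(f"bgA{i:05d}", _to_str(codes)))
        rows_a.append({"transcript": f"bgA{i:05d}", "motif_start": pos,
                       "mismatches": mism, "partner_offset": partner_offset})

    set_b_transcripts, set_b_peaks, rows_b = {}, [], []
    lo, hi = config.peak_len_range
    for i in range(config.n_background):
        tid = f"bgB{i:05d}"
        peak_len = int(rng.integers(lo, hi + 1))
        peak_start = 100
        peak_end = peak_start + peak_len
        distal_start = peak_end + config.setb_distal_distance + config.flank
        tlen = distal_start + k + config.flank + 100
        codes = _sample_bases(rng, tlen, config.background_freqs)
        # bound region: motif inside the peak
        pos = peak_start + int(rng.integers(0, peak_len - k + 1))
        planted, _ = _noised_motif(rng, config.motif, config.substitution_rate)
        codes[pos : pos + k] = [code_of[c] for c in planted]
        # distal occurrence, exact
        codes[distal_start : distal_start + k] = [code_of[c] for c in config.motif]
        set_b_transcripts[tid] = _to_str(codes)
        set_b_peaks.append(PeakInterval(tid, peak_start, peak_end, "+"))
        rows_b.append({"transcript": tid, "peak_motif_start": pos,
                       "distal_start": distal_start,
                       "distance": distal_start - peak_end})
    return BackgroundPools(set_a, pd.DataFrame(rows_a), set_b_transcripts,
                           set_b_peaks, pd.DataFrame(rows_b))


def null_corpus(config: SimulationConfig, lengths: Sequence[int]
                ) -> list[str]:
    """Random sequences matching a peak length multiset, drawn from the
    background composition with no planted signal."""
    rng = _rng(config, 3)
    return [_to_str(_sample_bases(rng, int(L), config.background_freqs))
            for L in lengths]
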