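"""Sequence-intrinsic feature scans used to probe stall-cause hypotheses.

Codon adaptation index (CAI) against a reference usage table, GC/GC3 sliding
profiles, G4Hunter-style G-quadruplex scoring, longest-ORF-to-element length
ratio, and codon/amino-acid lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "GENETIC_CODE",
    "FeatureTrack",
    "cai_profile",
    "gc_profiles",
    "g4_scan",
    "orf_length_ratio",
    "codons_at",
]

# standard nuclear code, with the three stops added as '*'
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

_SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    _SYNONYMOUS.setdefault(_aa, []).append(_codon)

# single-codon families and stops carry no usage information for CAI
_CAI_EXCLUDED = {c for c, aa in GENETIC_CODE.items() if aa in ("M", "W", "*")}

# relative adaptiveness floor for codons unobserved in the reference set
W_FLOOR = 0.01


@dataclass
class FeatureTrack:
    """A per-position (nt- or codon-indexed) real-valued feature track."""

    kind: Literal["cai", "gc", "gc3", "g4"]
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.kind} track contains non-finite values")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.kind} track positions must be strictly increasing")


def _split_codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def relative_adaptiveness(reference_usage: Mapping[str, float]) -> dict[str, float]:
    """w(codon) = usage frequency / max frequency in its synonymous family."""
    w: dict[str, float] = {}
    for aa, family in _SYNONYMOUS.items():
        if aa == "*":
            continue
        fmax = max(reference_usage.get(c, 0.0) for c in family)
        for c in family:
            if fmax == 0:
                w[c] = 1.0  # family absent from the reference: uninformative
            else:
                w[c] = max(reference_usage.get(c, 0.0) / fmax, W_FLOOR)
    return w


def cai_profile(
    cds: str, reference_usage: Mapping[str, float]
) -> tuple[FeatureTrack, float]:
    """Per-codon relative adaptiveness and the geometric-mean CAI of a CDS.

    Met, Trp and stop codons are excluded from the geometric mean (their
    families are invariant); the per-codon track still reports their w of 1.
    """
    w = relative_adaptiveness(reference_usage)
    codons = _split_codons(cds)
    values, logsum, n_contrib = [], 0.0, 0
    for c in codons:
        wc = w.get(c, 1.0) if GENETIC_CODE.get(c, "*") != "*" else 1.0
        values.append(wc)
        if c in GENETIC_CODE and c not in _CAI_EXCLUDED:
            logsum += math.log(wc)
            n_contrib += 1
    if n_contrib == 0:
        raise ValueError("CDS has no CAI-informative codons (only Met/Trp/stop)")
    cai = math.exp(logsum / n_contrib)
    track = FeatureTrack("cai", np.arange(1, len(codons) + 1), np.array(values))
    return track, cai


def gc_profiles(cds: str, window_codons: int = 1) -> tuple[FeatureTrack, FeatureTrack]:
    """Sliding-window GC and GC3 (third-position G/C) per-codon profiles.

    The window is centred on each codon and truncated at the CDS ends.
    """
    codons = _split_codons(cds)
    gc = np.array([sum(b in "GC" for b in c) / 3.0 for c in codons])
    gc3 = np.array([1.0 if c[2] in "GC" else 0.0 for c in codons])
    half = max(0, (window_codons - 1) // 2)
    n = len(codons)
    gc_w = np.array([gc[max(0, i - half) : min(n, i + half + 1)].mean() for i in range(n)])
    gc3_w = np.array([gc3[max(0, i - half) : min(n, i + half + 1)].mean() for i in range(n)])
    pos = np.arange(1, n + 1)
    return FeatureTrack("gc", pos, gc_w), FeatureTrack("gc3", pos, gc3_w)


def _g4_base_scores(seq: str) -> np.ndarray:
    """G4Hunter-style base scores: runs of G score +min(run, 4) per base,
    runs of C score -min(run, 4) per base, everything else 0."""
    seq = seq.upper()
    scores = np.zeros(len(seq))
    i = 0
    while i < len(seq):
        b = seq[i]
        if b in "GC":
            j = i
            while j < len(seq) and seq[j] == b:
                j += 1
            run = j - i
            val = min(run, 4) * (1 if b == "G" else -1)
            scores[i:j] = val
            i = j
        else:
            i += 1
    return scores


def g4_scan(
    seq: str, window: int = 25, threshold: float = 1.2
) -> tuple[FeatureTrack, list[tuple[int, int]]]:
    """Windowed-mean G-quadruplex scores and hotspot intervals.

    Returns the per-window-centre track (1-based positions of window starts)
    and the maximal intervals whose window mean is >= threshold with positive
    sign, i.e. G-rich on the given (coding) strand.
    """
    if window < 1 or window > len(seq):
        raise ValueError("window must lie in [1, len(seq)]")
    base = _g4_base_scores(seq)
    kernel = np.ones(window) / window
    means = np.convolve(base, kernel, mode="valid")
    pos = np.arange(1, len(means) + 1)
    hotspots: list[tuple[int, int]] = []
    in_spot = False
    for k, v in enumerate(means):
        if v >= threshold and not in_spot:
            in_spot, start = True, k
        elif v < threshold and in_spot:
            in_spot = False
            hotspots.append((start + 1, k + window))  # 1-based inclusive nt span
    if in_spot:
        hotspots.append((start + 1, len(seq)))
    return FeatureTrack("g4", pos, means), hotspots


def orf_length_ratio(element_seq: str) -> float:
    """Longest ATG-to-stop ORF (both strands, all frames) over element length."""
    seq = element_seq.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty element sequence")
    best = 0
    for s in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if start is None and codon == "ATG":
                    start = i
                elif start is not None and codon in ("TAA", "TAG", "TGA"):
                    best = max(best, i + 3 - start)  # stop codon included
                    start = None
    return best / n


def codons_at(cds: str, indices: Sequence[int]) -> list[tuple[str, str]]:
    """Look up (triplet, one-letter amino acid) at 1-based codon indices."""
    codons = _split_codons(cds)
    out = []
    for idx in indices:
        if not 1 <= idx <= len(codons):
            raise IndexError(f"codon index {idx} outside CDS of {len(codons)} codons")
        c = codons[idx - 1]
        out.append((c, GENETIC_CODE.get(c, "X")))
    return out
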