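"""P-site offset estimation, P-site assignment and periodicity QC.

Length-dependent 5'->P-site offsets are estimated from the 5'-end coverage
profile around annotated start codons: elongating ribosomes leave no
footprints upstream of the start, so for each read length the offset is the
largest candidate distance that still carries substantial start-aligned
signal.  Reads of lengths that cannot be calibrated are dropped, not guessed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tds.ioformats import AlignedRead, TranscriptModel

__all__ = ["PsiteOffsets", "CodonOccupancy", "estimate_offsets", "assign_psites", "periodicity_qc"]

logger = logging.getLogger(__name__)

OFFSET_MARGIN = 6  # candidate offsets are searched in [6, length - 6]
NEAR_TIE_FRACTION = 0.5  # candidates within this fraction of the max are "ties"


@dataclass(frozen=True)
class PsiteOffsets:
    """Estimated 5'->P-site offsets per read length, with supporting counts."""

    offsets: dict[int, int]
    support: dict[int, float]

    def __post_init__(self) -> None:
        for ln, off in self.offsets.items():
            if not 0 < off < ln:
                raise ValueError(f"offset {off} invalid for read length {ln}")


@dataclass
class CodonOccupancy:
    """Weighted P-site counts per sense codon of one isoform's CDS.

    ``counts[k]`` is the pooled-frame P-site weight on codon k+1; the stop
    codon is excluded (it is excluded from all downstream statistics).
    """

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError(f"{self.transcript_id}: occupancy counts must be finite, >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_codons(self) -> int:
        return len(self.counts)

    @property
    def coverage_fraction(self) -> float:
        if self.n_codons == 0:
            return 0.0
        return float(np.count_nonzero(self.counts)) / self.n_codons


def _reads_by_ref(reads: Iterable[AlignedRead]) -> dict[str, list[AlignedRead]]:
    by_ref: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_ref[r.ref].append(r)
    return by_ref


def estimate_offsets(
    reads: Iterable[AlignedRead],
    models: Sequence[TranscriptModel],
    min_support: float = 100,
) -> PsiteOffsets:
    """Estimate the 5'->P-site offset per read length from start-codon metagenes.

    For each length L, candidate offsets d in [6, L-6] are scored by the
    weighted count of reads whose 5' end lies d nt upstream of an annotated
    start codon.  Because uniform elongation puts comparable mass at
    d_true, d_true - 3, d_true - 6, ... while nothing maps upstream of the
    start, the offset is taken as the largest candidate whose count reaches
    half of the maximum.  Lengths whose start-proximal support is below
    ``min_support`` are omitted.
    """
    model_by_id = {m.transcript_id: m for m in models if m.has_cds}
    counts: dict[int, defaultdict[int, float]] = defaultdict(lambda: defaultdict(float))
    support: dict[int, float] = defaultdict(float)
    for r in reads:
        m = model_by_id.get(r.ref)
        if m is None or r.strand != "+":
            continue
        L = r.length
        d = m.cds_start - r.start  # offset that would place the P-site on the start
        if OFFSET_MARGIN <= d <= L - OFFSET_MARGIN:
            counts[L][d] += r.weight
            support[L] += r.weight

    offsets: dict[int, int] = {}
    kept_support: dict[int, float] = {}
    for L, by_d in counts.items():
        if support[L] < min_support:
            continue
        cmax = max(by_d.values())
        candidates = [d for d, c in by_d.items() if c >= NEAR_TIE_FRACTION * cmax]
        offsets[L] = max(candidates)
        kept_support[L] = support[L]
    if not offsets:
        raise ValueError("no calibratable read length: no length reached min_support")
    return PsiteOffsets(offsets=offsets, support=kept_support)


def assign_psites(
    reads: Iterable[AlignedRead],
    offsets: PsiteOffsets,
    models: Sequence[TranscriptModel],
) -> dict[str, CodonOccupancy]:
    """Assign P-sites and accumulate per-codon occupancy for each isoform.

    P-site nt = 5' end + offset(length); all three frames are pooled into the
    codon the P-site falls in.  Reads of uncalibrated lengths, and P-sites
    outside the CDS or on the stop codon, are discarded.
    """
    model_by_id = {m.transcript_id: m for m in models if m.has_cds}
    occ = {
        tid: np.zeros(m.n_codons - 1)  # sense codons only; stop excluded
        for tid, m in model_by_id.items()
    }
    dropped_uncalibrated = 0.0
    for r in reads:
        m = model_by_id.get(r.ref)
        if m is None:
            continue
        off = offsets.offsets.get(r.length)
        if off is None:
            dropped_uncalibrated += r.weight
            continue
        psite = r.five_prime + off if r.strand == "+" else r.five_prime - off
        if not m.cds_start <= psite < m.cds_end:
            continue
        codon = (psite - m.cds_start) // 3  # 0-based
        if codon >= m.n_codons - 1:  # stop codon
            continue
        occ[r.ref][codon] += r.weight
    if dropped_uncalibrated:
        logger.info("dropped %.1f read weight of uncalibratable lengths", dropped_uncalibrated)
    return {tid: CodonOccupancy(tid, c) for tid, c in occ.items()}


def periodicity_qc(
    reads: Iterable[AlignedRead],
    offsets: PsiteOffsets,
    models: Sequence[TranscriptModel],
    metagene_window: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frame fractions of assigned P-sites and a start-codon 5'-end metagene.

    Returns ``(frames, metagene)``: frame-0/1/2 fractions per read length and
    pooled, and the per-length counts of 5' ends in [-window, +window] around
    annotated start codons.
    """
    model_by_id = {m.transcript_id: m for m in models if m.has_cds}
    frame_counts: dict[int | str, np.ndarray] = defaultdict(lambda: np.zeros(3))
    meta: dict[int, defaultdict[int, float]] = defaultdict(lambda: defaultdict(float))
    n_assigned = 0.0
    for r in reads:
        m = model_by_id.get(r.ref)
        if m is None:
            continue
        rel = r.five_prime - m.cds_start
        if -metagene_window <= rel <= metagene_window:
            meta[r.length][rel] += r.weight
        off = offsets.offsets.get(r.length)
        if off is None:
            continue
        psite = r.five_prime + off if r.strand == "+" else r.five_prime - off
        if not m.cds_start <= psite < m.cds_end:
            continue
        frame = (psite - m.cds_start) % 3
        frame_counts[r.length][frame] += r.weight
        frame_counts["pooled"][frame] += r.weight
        n_assigned += r.weight
    if n_assigned == 0:
        raise ValueError("zero assigned P-sites; cannot compute periodicity")
    frames = pd.DataFrame(
        [
            {"length": ln, "frame0": c[0] / c.sum(), "frame1": c[1] / c.sum(),
             "frame2": c[2] / c.sum(), "n": c.sum()}
            for ln, c in sorted(frame_counts.items(), key=lambda kv: str(kv[0]))
            if c.sum() > 0
        ]
    )
    meta_rows = [
        {"length": ln, "position": pos, "count": cnt}
        for ln, by_pos in meta.items()
        for pos, cnt in sorted(by_pos.items())
    ]
    metagene = pd.DataFrame(meta_rows, columns=["length", "position", "count"])
    return frames, metagene
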