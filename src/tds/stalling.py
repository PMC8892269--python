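"""Stalling scores, consecutive-codon fractions, percentile ranking and codon stats.

The stalling score at a codon is the ratio of its observed P-site count to the
transcript-wide mean occupancy, so a uniform transcript scores 1 everywhere
and the mean score over included codons is 1 by construction.  Stop codons,
and di-codons containing a stop, are excluded; qualification requires the most
translated isoform per gene with P-site coverage on at least 70% of its
codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tds.ioformats import TranscriptModel
from tds.psite import CodonOccupancy
from tds.seqscan import GENETIC_CODE

__all__ = [
    "StallReport",
    "CodonStats",
    "select_isoforms",
    "stall_scores",
    "rank_transcripts",
    "dwell_and_usage",
    "COVERAGE_THRESHOLD",
]

COVERAGE_THRESHOLD = 0.70


@dataclass
class StallReport:
    """Per-codon stalling scores and the maximal stall event of one isoform."""

    transcript_id: str
    scores: np.ndarray
    max_score: float = 0.0
    max_codon: int = 0  # 1-based
    pair: tuple[int, int] = (0, 0)  # 1-based (i, i+1)
    pair_fraction: float = 0.0
    percentile: float | None = None
    qualified: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class CodonStats:
    """Codon dwell times and codon usage over the translated gene set."""

    dwell: dict[str, float]
    usage: dict[str, float]


def select_isoforms(
    occupancies: Mapping[str, CodonOccupancy],
    models: Sequence[TranscriptModel],
) -> tuple[dict[str, CodonOccupancy], dict[str, str]]:
    """Keep the most translated isoform per gene if >= 70% of codons are covered.

    Returns the qualified subset and a map of excluded transcript -> reason.
    """
    model_by_id = {m.transcript_id: m for m in models}
    by_gene: dict[str, list[str]] = {}
    for tid in occupancies:
        m = model_by_id.get(tid)
        if m is None:
            continue
        by_gene.setdefault(m.gene_id, []).append(tid)
    kept: dict[str, CodonOccupancy] = {}
    excluded: dict[str, str] = {}
    for gene, tids in by_gene.items():
        best = max(tids, key=lambda t: (occupancies[t].total, t))
        for t in tids:
            if t != best:
                excluded[t] = "not_most_translated"
        occ = occupancies[best]
        if occ.total == 0:
            excluded[best] = "no_reads"
        elif occ.coverage_fraction >= COVERAGE_THRESHOLD:
            kept[best] = occ
        else:
            excluded[best] = "coverage"
    return kept, excluded


def stall_scores(occupancy: CodonOccupancy) -> StallReport:
    """Per-codon stalling scores and the strongest single/di-codon event.

    Scores are observed/expected counts where the expectation is the mean over
    all sense codons.  The di-codon search excludes the last sense codon (the
    stop-containing di-codon); the two-codon fraction is the pair's share of
    the transcript's total occupancy.
    """
    counts = occupancy.counts
    n = len(counts)
    total = counts.sum()
    if total == 0 or n == 0:
        return StallReport(
            occupancy.transcript_id, np.zeros(n), qualified=False, reason="no_reads"
        )
    mean = total / n
    scores = counts / mean
    max_idx = int(np.argmax(scores))
    pair_i, pair_fraction = 0, 0.0
    if n >= 3:
        pair_sums = counts[:-2] + counts[1:-1]  # pairs (i, i+1), i+1 < last codon
        pair_i = int(np.argmax(pair_sums))
        pair_fraction = float(pair_sums[pair_i] / total)
    elif n == 2:
        pair_i, pair_fraction = 0, float((counts[0] + counts[1]) / total)
    return StallReport(
        transcript_id=occupancy.transcript_id,
        scores=scores,
        max_score=float(scores[max_idx]),
        max_codon=max_idx + 1,
        pair=(pair_i + 1, pair_i + 2),
        pair_fraction=pair_fraction,
    )


def rank_transcripts(reports: Sequence[StallReport]) -> dict[str, float]:
    """Transcriptome percentile of each stall: the percentage of qualified
    transcripts with a strictly larger maximal stalling score."""
    qualified = [r for r in reports if r.qualified]
    if not qualified:
        raise ValueError("empty qualified set; cannot rank")
    maxima = np.array([r.max_score for r in qualified])
    out: dict[str, float] = {}
    for r in qualified:
        pct = 100.0 * float(np.sum(maxima > r.max_score)) / len(qualified)
        r.percentile = pct
        out[r.transcript_id] = pct
    return out


def dwell_and_usage(
    occupancies: Mapping[str, CodonOccupancy],
    models: Sequence[TranscriptModel],
) -> CodonStats:
    """Codon dwell times and codon usage over the qualified (translated) set.

    Dwell time of a codon is the mean log-normalized occupancy over every
    (transcript, position) instance of that codon: occupancies are divided by
    the transcript mean and a pseudo-count of half a read (0.5/mean) is added
    inside the log.  Usage is the codon frequency over qualified CDSs.  Stop
    codons appear in neither map.
    """
    model_by_id = {m.transcript_id: m for m in models}
    dwell_sum: dict[str, float] = {}
    dwell_n: dict[str, int] = {}
    usage_count: dict[str, float] = {c: 0.0 for c, aa in GENETIC_CODE.items() if aa != "*"}
    for tid, occ in occupancies.items():
        m = model_by_id.get(tid)
        if m is None or not m.has_cds or occ.total == 0:
            continue
        cds = m.cds_sequence
        mean = occ.total / occ.n_codons
        lognorm = np.log((occ.counts + 0.5) / mean)
        for k in range(occ.n_codons):
            codon = cds[3 * k : 3 * k + 3]
            if GENETIC_CODE.get(codon, "*") == "*":
                continue
            dwell_sum[codon] = dwell_sum.get(codon, 0.0) + float(lognorm[k])
            dwell_n[codon] = dwell_n.get(codon, 0) + 1
            usage_count[codon] += 1.0
    total_usage = sum(usage_count.values())
    usage = {
        c: (v / total_usage if total_usage > 0 else 0.0) for c, v in usage_count.items()
    }
    dwell = {c: dwell_sum[c] / dwell_n[c] for c in dwell_sum}
    return CodonStats(dwell=dwell, usage=usage)


def reports_to_frame(reports: Sequence[StallReport]) -> pd.DataFrame:
    """Flatten stall reports to one row per isoform (1-based codon indices)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "max_score": r.max_score,
                "max_codon": r.max_codon,
                "pair_start": r.pair[0],
                "pair_end": r.pair[1],
                "pair_fraction": r.pair_fraction,
                "percentile": r.percentile,
                "qualified": r.qualified,
                "reason": r.reason,
            }
            for r in reports
        ]
    )
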