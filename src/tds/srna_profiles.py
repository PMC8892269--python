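"""Size-class/strand-resolved siRNA coverage, isoform attribution and onset.

Profiles are browser-style stacked coverage tracks in reads per million (RPM),
stratified by the DCL-diagnostic size classes 21, 22 and 24 nt (plus "other")
and by strand.  The onset of an siRNA pattern is located by least-squares
single change-point fitting of a two-level piecewise-constant model to the
pooled read-start histogram of the 21/22-nt classes: read starts, unlike
coverage, form a sharp step at the 5' boundary of the pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from tds.ioformats import AlignedRead, CoverageTrack, TranscriptModel

__all__ = [
    "SrnaProfile",
    "SIZE_CLASSES",
    "size_profile",
    "attribute_isoform",
    "onset_changepoint",
    "dependence_ratio",
]

SIZE_CLASSES = (21, 22, 24)


def _size_class(length: int) -> int | str:
    return length if length in SIZE_CLASSES else "other"


@dataclass
class SrnaProfile:
    """Per-position RPM coverage and read-start counts over one locus.

    ``coverage[(size_class, strand)]`` holds RPM over every covered position;
    ``starts[(size_class, strand)]`` holds RPM at each read's leftmost
    position only (used for onset detection).
    """

    locus: str
    length: int
    library_total: float
    coverage: dict[tuple[int | str, str], np.ndarray] = field(default_factory=dict)
    starts: dict[tuple[int | str, str], np.ndarray] = field(default_factory=dict)

    def pooled_coverage(
        self, classes: Iterable[int | str] = (21, 22), strands: str = "+-"
    ) -> np.ndarray:
        out = np.zeros(self.length)
        for cls in classes:
            for strand in strands:
                out += self.coverage.get((cls, strand), 0.0)
        return out

    def pooled_starts(
        self, classes: Iterable[int | str] = (21, 22), strands: str = "+-"
    ) -> np.ndarray:
        out = np.zeros(self.length)
        for cls in classes:
            for strand in strands:
                out += self.starts.get((cls, strand), 0.0)
        return out

    def to_tracks(self) -> list[CoverageTrack]:
        return [
            CoverageTrack(self.locus, vals, 0, f"sRNA_{cls}nt_{strand}")
            for (cls, strand), vals in sorted(self.coverage.items(), key=str)
        ]


def size_profile(
    reads: Iterable[AlignedRead], locus: str, locus_length: int, library_total: float
) -> SrnaProfile:
    """Stacked size-class/strand coverage in RPM over ``[0, locus_length)``.

    Each read adds weight * 1e6 / library_total to every position it covers
    (clipped at the locus bounds) in its size class and strand.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    scale = 1e6 / library_total
    profile = SrnaProfile(locus, locus_length, library_total)
    for r in reads:
        if r.ref != locus:
            continue
        key = (_size_class(r.length), r.strand)
        if key not in profile.coverage:
            profile.coverage[key] = np.zeros(locus_length)
            profile.starts[key] = np.zeros(locus_length)
        a, b = max(0, r.start), min(locus_length, r.end)
        if a < b:
            profile.coverage[key][a:b] += r.weight * scale
            profile.starts[key][a] += r.weight * scale
    return profile


def attribute_isoform(
    reads: Iterable[AlignedRead],
    models: Sequence[TranscriptModel],
) -> dict[str, float]:
    """Diagnostic attribution of transcript-space reads to the two isoforms.

    Reads on the spliced isoform crossing the exon1-exon2 junction point are
    spliced-isoform evidence; reads on the full-length isoform overlapping the
    intron are unspliced evidence; reads on the full-length isoform starting
    3' of the PCPA site (the spliced isoform's 3' end) are unspliced-only
    evidence; everything else is ambiguous.
    """
    spliced = next((m for m in models if len(m.exons) >= 2), None)
    full = next((m for m in models if len(m.exons) == 1), None)
    if spliced is None or full is None:
        raise ValueError("models lack intron/PCPA annotation (need spliced + full isoforms)")
    iv = sorted(spliced.exons)
    donor, acceptor = iv[0][1], iv[1][0]  # genomic intron bounds
    junction = iv[0][1] - iv[0][0]  # transcript position of exon1 end (spliced)
    # map genomic intron/PCPA bounds into full-length transcript coordinates
    donor_full = full.genomic_to_transcript(donor - 1)
    acceptor_full = full.genomic_to_transcript(acceptor)
    pcpa_full = full.genomic_to_transcript(iv[-1][1] - 1)
    if donor_full is None or acceptor_full is None or pcpa_full is None:
        raise ValueError("intron/PCPA bounds fall outside the full-length isoform")
    counts = {"spliced": 0.0, "unspliced": 0.0, "unspliced_only_region": 0.0, "ambiguous": 0.0}
    for r in reads:
        if r.ref == spliced.transcript_id and r.start < junction < r.end:
            counts["spliced"] += r.weight
        elif r.ref == full.transcript_id and r.start > pcpa_full:
            counts["unspliced_only_region"] += r.weight
        elif r.ref == full.transcript_id and r.start < acceptor_full and r.end > donor_full + 1:
            # overlaps the intron [donor_full + 1, acceptor_full)
            counts["unspliced"] += r.weight
        else:
            counts["ambiguous"] += r.weight
    return counts


def _step_fit(y: np.ndarray) -> tuple[int, float, float]:
    """Least-squares single change-point fit of a two-level step to ``y``.

    Returns (breakpoint index t, SSE of the step model, SSE of the flat
    model); the step model is mean(y[:t]) before t and mean(y[t:]) from t.
    """
    n = len(y)
    c = np.cumsum(y)
    c2 = np.cumsum(y * y)
    total, total2 = c[-1], c2[-1]
    t = np.arange(1, n)  # candidate breakpoints: 1..n-1
    left_sum = c[t - 1]
    right_sum = total - left_sum
    sse = (total2 - left_sum**2 / t - right_sum**2 / (n - t))
    best = int(np.argmin(sse))
    sse_flat = float(total2 - total**2 / n)
    return int(t[best]), float(sse[best]), sse_flat


def onset_changepoint(
    profile: SrnaProfile,
    classes: Iterable[int | str] = (21, 22),
    min_sse_reduction: float = 0.25,
) -> int | None:
    """Locate the 5' onset of the siRNA pattern, or None if there is no step.

    Fits a single change-point, two-level piecewise-constant model by least
    squares to the pooled both-strand read-start histogram of the chosen size
    classes and returns the 1-based breakpoint, provided the SSE reduction
    versus the flat model exceeds ``min_sse_reduction``.
    """
    y = profile.pooled_starts(classes=classes, strands="+-")
    if len(y) < 2 or y.sum() == 0:
        return None
    t, sse_step, sse_flat = _step_fit(y)
    if sse_flat <= 0:
        return None
    if (sse_flat - sse_step) / sse_flat <= min_sse_reduction:
        return None
    return t + 1  # 1-based position where the high level begins


def dependence_ratio(
    profile_a: SrnaProfile,
    profile_b: SrnaProfile,
    pseudocount: float = 0.01,
) -> dict[int | str, float]:
    """Per-size-class log2 ratio of locus-summed RPM between two profiles.

    Stands in for a genotype comparison (e.g. WT vs rdr6): log2((A + q)/(B + q))
    of the summed coverage per size class over the locus.
    """
    classes = {cls for cls, _ in profile_a.coverage} | {cls for cls, _ in profile_b.coverage}
    out: dict[int | str, float] = {}
    for cls in classes:
        a = float(profile_a.pooled_coverage(classes=[cls]).sum())
        b = float(profile_b.pooled_coverage(classes=[cls]).sum())
        out[cls] = math.log2((a + pseudocount) / (b + pseudocount))
    return out
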