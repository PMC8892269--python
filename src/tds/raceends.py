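"""Mapping of RACE-clone 5' ends and 5'-end track arithmetic.

Clones of 5'OH 3'-cleavage fragments are anchored to the reference by their
first ``anchor_k`` bases (Hamming distance <= ``max_mismatch``, unique hit
required); mapped 5' ends are tallied in sliding windows to find the modal
breakage interval, and nucleotide positions are converted to codon indices
with codon = ceil(nt / 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from tds.ioformats import AlignedRead, CoverageTrack, NamedSequence

__all__ = [
    "CloneEnd",
    "map_clone_5p",
    "modal_end_fraction",
    "nt_to_codon",
    "end5_track",
]


@dataclass(frozen=True)
class CloneEnd:
    """Anchoring result for one clone; ``end5`` is 1-based on the reference."""

    clone_id: str
    mapped: bool
    end5: int | None = None
    match_len: int = 0
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mapped and (self.end5 is None or self.end5 < 1):
            raise ValueError(f"{self.clone_id}: mapped clone needs end5 >= 1")


def _hamming_hits(anchor: str, reference: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(position, mismatches) of every anchor occurrence within tolerance."""
    k = len(anchor)
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    n = len(ref) - k + 1
    if n <= 0:
        return []
    # sliding-window mismatch counts via a strided view; fine at locus scale
    windows = np.lib.stride_tricks.sliding_window_view(ref, k)
    mism = (windows != a).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(p), int(mism[p])) for p in hits]


def map_clone_5p(
    clones: Iterable[NamedSequence],
    reference: NamedSequence | str,
    anchor_k: int = 25,
    max_mismatch: int = 1,
    adapter: str = "",
) -> list[CloneEnd]:
    """Anchor each clone's 5' end on the reference.

    An optional 5' adapter prefix is stripped, trailing Ns (Sanger tail) are
    trimmed, and the clone's first ``anchor_k`` bases are located on the
    reference allowing <= ``max_mismatch`` mismatches.  Clones whose anchor is
    absent, ambiguous (multiple hits) or too short are reported unmapped.
    """
    ref = reference.seq if isinstance(reference, NamedSequence) else reference
    if len(ref) < anchor_k:
        raise ValueError(f"reference shorter than anchor_k={anchor_k}")
    out: list[CloneEnd] = []
    for clone in clones:
        seq = clone.seq
        if adapter and seq.startswith(adapter):
            seq = seq[len(adapter):]
        seq = seq.rstrip("N")
        if len(seq) < anchor_k:
            out.append(CloneEnd(clone.id, mapped=False))
            continue
        anchor = seq[:anchor_k]
        hits = _hamming_hits(anchor, ref, max_mismatch)
        if len(hits) != 1:
            out.append(CloneEnd(clone.id, mapped=False))
            continue
        pos, mism = hits[0]
        out.append(
            CloneEnd(clone.id, mapped=True, end5=pos + 1, match_len=anchor_k, mismatches=mism)
        )
    return out


def modal_end_fraction(
    ends: Sequence[CloneEnd] | Sequence[int], window: int = 2
) -> tuple[tuple[int, int], int, float]:
    """Modal ``window``-nt interval of mapped 5' ends.

    Returns ((start, end) 1-based inclusive, count in the interval, count as a
    fraction of all mapped ends).  Ties go to the leftmost interval.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    positions = sorted(
        e.end5 for e in ends if isinstance(e, CloneEnd) and e.mapped
    ) if ends and isinstance(ends[0], CloneEnd) else sorted(int(e) for e in ends)
    if not positions:
        raise ValueError("no mapped 5' ends to tally")
    pos = np.array(positions)
    best_start, best_count = positions[0], -1
    for s in range(positions[0] - window + 1, positions[-1] + 1):
        count = int(np.sum((pos >= s) & (pos <= s + window - 1)))
        if count > best_count:
            best_start, best_count = s, count
    return (best_start, best_start + window - 1), best_count, best_count / len(positions)


def nt_to_codon(orf_nt: int) -> int:
    """1-based ORF nucleotide position -> 1-based codon index (ceil(nt/3))."""
    if orf_nt < 1:
        raise ValueError("ORF nucleotide positions are 1-based")
    return math.ceil(orf_nt / 3)


def end5_track(reads: Iterable[AlignedRead], locus: str, locus_length: int) -> dict[str, CoverageTrack]:
    """Per-strand 5'-end count tracks: each read's weight at its 5'-most
    position only (the rightmost coordinate for minus-strand reads)."""
    values = {"+": np.zeros(locus_length), "-": np.zeros(locus_length)}
    for r in reads:
        if r.ref != locus:
            continue
        p = r.five_prime
        if 0 <= p < locus_length:
            values[r.strand][p] += r.weight
    return {
        strand: CoverageTrack(locus, vals, 0, f"end5_{strand}")
        for strand, vals in values.items()
    }
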