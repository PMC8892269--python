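"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions used throughout the package:

* every internal coordinate is 0-based, half-open;
* every user-facing report is 1-based, inclusive (e.g. "nucleotides 447-448");
* transcript-space positions run 5'->3' along the spliced transcript.

Aligned reads can come from a SAM subset (via :mod:`pysam`) or from a plain
6-column tabular format (``read_id  ref  start  length  strand  n_hits``,
tab-separated, 0-based start) that exists so tests and synthetic data need no
binary BAM dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NamedSequence",
    "TranscriptModel",
    "AlignedRead",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_transcript_models",
    "read_alignments",
    "write_tabular_alignments",
    "write_bedgraph",
    "read_bedgraph",
]

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide sequence, uppercase over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("NamedSequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one isoform with genomic and transcript coordinates.

    ``exons`` are genomic (0-based, half-open) intervals listed in transcript
    order: ascending genomic position on '+', descending on '-'.  ``cds_start``
    and ``cds_end`` are transcript-local (0-based, half-open) and include the
    stop codon; they are ``None`` for non-coding isoforms.  ``sequence`` is the
    spliced, strand-corrected nucleotide string.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    sequence: str = ""
    qualified: bool = True
    disqualify_reason: str | None = None

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ValueError(f"{self.transcript_id}: '+' exons not in ascending order")
        else:
            if starts != sorted(starts, reverse=True):
                raise ValueError(f"{self.transcript_id}: '-' exons not in descending order")
        # exons must not overlap
        iv = sorted((s, e) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != exon sum {self.length}"
            )
        if self.cds_start is not None:
            if self.cds_end is None or self.cds_end <= self.cds_start:
                raise ValueError(f"{self.transcript_id}: bad CDS bounds")
            if (self.cds_end - self.cds_start) % 3 != 0:
                # flagged, not fatal: transcript kept but marked non-qualifying
                warnings.warn(
                    f"{self.transcript_id}: CDS length not divisible by 3; flagged non-qualifying"
                )
                self.qualified = False
                self.disqualify_reason = "cds_length_not_multiple_of_3"

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.qualified

    @property
    def n_codons(self) -> int:
        """Number of CDS codons including the stop codon."""
        if self.cds_start is None or self.cds_end is None:
            return 0
        return (self.cds_end - self.cds_start) // 3

    @property
    def cds_sequence(self) -> str:
        if self.cds_start is None:
            return ""
        return self.sequence[self.cds_start : self.cds_end]

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to a transcript-local one; None if intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                if self.strand == "+":
                    return offset + (gpos - s)
                return offset + (e - 1 - gpos)
            offset += e - s
        return None


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read in either genome or transcript space.

    ``start`` is the leftmost (reference-ascending) 0-based position of the
    aligned span; ``weight`` is the fractional multimapper weight, 1/n_hits
    under the fractional counting policy.
    """

    read_id: str
    ref: str
    start: int
    length: int
    strand: Literal["+", "-"]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"read {self.read_id}: negative start")
        if self.length < 1:
            raise ValueError(f"read {self.read_id}: non-positive length")
        if not (0 < self.weight <= 1):
            raise ValueError(f"read {self.read_id}: weight {self.weight} outside (0, 1]")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """5'-most reference position (rightmost coordinate on '-')."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CoverageTrack:
    """A labelled per-position real-valued track anchored at ``offset``."""

    ref: str
    values: np.ndarray
    offset: int = 0
    label: str = "coverage"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"track {self.label!r}: values must be finite and >= 0")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[NamedSequence]:
    """Read a FASTA file into NamedSequences (uppercased, U mapped to T)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    out: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(NamedSequence(rec.id, str(rec.seq).upper().replace("U", "T")))
    return out


def write_fasta(seqs: Iterable[NamedSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript models (GFF3 / BED12)

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _spliced_sequence(chrom_seq: str, exons: Sequence[tuple[int, int]], strand: str) -> str:
    # exons arrive in transcript order; concatenate in genomic-ascending order
    iv = sorted(exons)
    genomic = "".join(chrom_seq[s:e] for s, e in iv)
    return genomic if strand == "+" else _revcomp(genomic)


def read_transcript_models(path: str | Path, genome: list[NamedSequence]) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12 and extract spliced sequences.

    Dialect is chosen by extension (.bed -> BED12, anything else -> GFF3).
    CDS coordinates are converted to transcript-local ones; minus-strand exons
    are reported in transcript order.
    """
    path = Path(path)
    chrom_seqs = {s.id: s.seq for s in genome}
    if path.suffix.lower() == ".bed":
        raw = _parse_bed12(path)
    else:
        raw = _parse_gff3(path)
    models: list[TranscriptModel] = []
    for tid, gid, chrom, strand, exons_genomic, cds_genomic in raw:
        if chrom not in chrom_seqs:
            raise ValueError(f"{path}: unknown chromosome {chrom!r} for {tid}")
        exons = sorted(exons_genomic)
        if strand == "-":
            exons = exons[::-1]
        seq = _spliced_sequence(chrom_seqs[chrom], exons, strand)
        cds_start = cds_end = None
        if cds_genomic is not None:
            gstart, gend = cds_genomic
            model_tmp = TranscriptModel(tid, gid, chrom, strand, list(exons), sequence=seq)
            # transcript-local CDS bounds from the genomic extremes of the CDS
            if strand == "+":
                t1 = model_tmp.genomic_to_transcript(gstart)
                t2 = model_tmp.genomic_to_transcript(gend - 1)
            else:
                t1 = model_tmp.genomic_to_transcript(gend - 1)
                t2 = model_tmp.genomic_to_transcript(gstart)
            if t1 is None or t2 is None:
                raise ValueError(f"{tid}: CDS bounds fall outside exons")
            cds_start, cds_end = t1, t2 + 1
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            models.append(
                TranscriptModel(
                    tid, gid, chrom, strand, list(exons),
                    cds_start=cds_start, cds_end=cds_end, sequence=seq,
                )
            )
    return models


def _parse_gff3(path: Path):
    """Minimal GFF3 parse of gene/mRNA/exon/CDS rows.

    gffutils is overkill for the flat two-level files this pipeline writes and
    reads, and its sqlite round-trip dominates runtime on tiny inputs; this
    keeps only the feature types the spec'd subset uses.
    """
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            s, e = int(start) - 1, int(end)
            if ftype in ("mRNA", "transcript"):
                tid = attr.get("ID")
                if tid is None:
                    raise ValueError(f"{path}: mRNA without ID")
                mrnas[tid] = {
                    "gene": attr.get("Parent", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                }
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent in mrnas:
                    mrnas[parent]["exons"].append((s, e))
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent in mrnas:
                    mrnas[parent]["cds"].append((s, e))
    out = []
    for tid, d in mrnas.items():
        exons = d["exons"] or d["cds"]
        cds = None
        if d["cds"]:
            cds = (min(s for s, _ in d["cds"]), max(e for _, e in d["cds"]))
        out.append((tid, d["gene"], d["chrom"], d["strand"], exons, cds))
    return out


def _parse_bed12(path: Path):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns")
            chrom, cstart, _cend, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(cstart + st, cstart + st + sz) for st, sz in zip(starts, sizes)]
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            out.append((name, name, chrom, strand, exons, cds))
    return out


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as flat GFF3 (mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            iv = sorted(m.exons)
            fh.write(
                f"{m.chrom}\ttds\tmRNA\t{iv[0][0] + 1}\t{iv[-1][1]}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for s, e in iv:
                fh.write(
                    f"{m.chrom}\ttds\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            if m.cds_start is not None:
                # project transcript-local CDS bounds back to genomic intervals
                for s, e in _transcript_interval_to_genomic(m, m.cds_start, m.cds_end):
                    fh.write(
                        f"{m.chrom}\ttds\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                        f"Parent={m.transcript_id}\n"
                    )


def _transcript_interval_to_genomic(
    model: TranscriptModel, tstart: int, tend: int
) -> list[tuple[int, int]]:
    pieces = []
    offset = 0
    for s, e in model.exons:
        ex_len = e - s
        lo, hi = max(tstart, offset), min(tend, offset + ex_len)
        if lo < hi:
            if model.strand == "+":
                pieces.append((s + (lo - offset), s + (hi - offset)))
            else:
                pieces.append((e - (hi - offset), e - (lo - offset)))
        offset += ex_len
    return sorted(pieces)


# ---------------------------------------------------------------------------
# Alignments

MultimapperPolicy = Literal["fractional", "primary"]


def read_alignments(
    path: str | Path,
    kind: Literal["sam", "tabular"] = "tabular",
    multimapper: MultimapperPolicy = "fractional",
) -> Iterator[AlignedRead]:
    """Stream AlignedReads from a SAM subset or the 6-column tabular format.

    Under the ``fractional`` policy each of a read's n reported alignments gets
    weight 1/n; under ``primary`` only primary alignments are kept, weight 1.
    """
    if kind == "sam":
        yield from _read_sam(path, multimapper)
    elif kind == "tabular":
        yield from _read_tabular(path, multimapper)
    else:
        raise ValueError(f"unknown alignment kind {kind!r}")


def _read_sam(path: str | Path, multimapper: MultimapperPolicy) -> Iterator[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        refs = set(sam.references)
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in refs:
                raise ValueError(f"{path}: reference {rec.reference_name!r} absent from header")
            if multimapper == "primary":
                if rec.is_secondary or rec.is_supplementary:
                    continue
                weight = 1.0
            else:
                nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
                weight = 1.0 / int(nh)
            # aligned span on the reference (M and N consume reference)
            length = rec.reference_length
            if length is None or length < 1:
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                ref=rec.reference_name,
                start=rec.reference_start,
                length=length,
                strand="-" if rec.is_reverse else "+",
                weight=weight,
            )


def _read_tabular(path: str | Path, multimapper: MultimapperPolicy) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(f)}")
            read_id, ref, start, length, strand, n_hits = (x.strip() for x in f)
            n = int(n_hits)
            if multimapper == "primary" and n > 1:
                # tabular rows are all reported alignments; under primary-only
                # keep the first row of a multimapper (n_hits encodes the rest)
                weight = 1.0
            else:
                weight = 1.0 / n
            yield AlignedRead(read_id, ref, int(start), int(length), strand, weight)  # type: ignore[arg-type]


def write_tabular_alignments(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tref\tstart\tlength\tstrand\tn_hits\n")
        for r in reads:
            n_hits = max(1, round(1.0 / r.weight))
            fh.write(f"{r.read_id}\t{r.ref}\t{r.start}\t{r.length}\t{r.strand}\t{n_hits}\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph (0-based half-open, equal-value runs merged,
    zero runs omitted)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.label}"\n')
        vals = track.values
        if len(vals) == 0:
            return
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                v = vals[run_start]
                if v != 0:
                    a = track.offset + run_start
                    b = track.offset + i
                    fh.write(f"{track.ref}\t{a}\t{b}\t{v:g}\n")
                run_start = i


def read_bedgraph(path: str | Path, label: str = "coverage") -> CoverageTrack:
    """Read a bedGraph back into a dense CoverageTrack (zeros filled in)."""
    rows = []
    ref = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            c, a, b, v = line.split()
            ref = c
            rows.append((int(a), int(b), float(v)))
    if not rows:
        return CoverageTrack(ref="", values=np.zeros(0), offset=0, label=label)
    offset = min(a for a, _, _ in rows)
    end = max(b for _, b, _ in rows)
    vals = np.zeros(end - offset)
    for a, b, v in rows:
        vals[a - offset : b - offset] = v
    return CoverageTrack(ref=ref, values=vals, offset=offset, label=label)
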