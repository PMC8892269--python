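"""Synthetic loci, reads, clones and count tables for pipeline testing.

The generator emulates a reactivated Ty1/Copia-like retroelement locus: a
single transcription unit producing an unspliced full-length mRNA and, via
splicing-coupled premature cleavage and polyadenylation (PCPA), a short
spliced isoform that carries the GAG open reading frame and is heavily
translated.  The short isoform harbours a programmable, discrete ribosome
stall on a chosen codon pair (proline-glycine by default) and spawns
double-stranded-region siRNAs strictly 3' of a breakage point inside its ORF.

Every simulator is a pure function of its configuration: the same
:class:`SimulationConfig` yields byte-identical output on rerun.  Truth tables
(true P-site codon per footprint, true clone class) are returned alongside the
reads so recovery tests do not have to re-infer them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from tds.ioformats import AlignedRead, NamedSequence, TranscriptModel

__all__ = [
    "SimulationConfig",
    "make_synthetic_locus",
    "simulate_rfp",
    "simulate_srna",
    "simulate_race_clones",
    "simulate_counts",
    "make_synthetic_transcriptome",
    "simulate_transcriptome_rfp",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# distinct salts so each simulator draws an independent, reproducible stream
_SALT_LOCUS, _SALT_RFP, _SALT_SRNA, _SALT_CLONES, _SALT_COUNTS, _SALT_TXOME = range(6)


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of the synthetic locus.

    Defaults mirror the biology being emulated: a ~300-codon GAG ORF with an
    intense stall on the proline-glycine codon pair 148-149 (the dwell factor
    of 80 puts ~35% of footprints on those two codons), siRNAs confined 3' of
    ORF nucleotide 447, footprints of 25-32 nt with 3-nt periodicity and
    length-dependent 5' offsets, and a 36-clone RACE experiment in which 5/6
    of clones start exactly at the breakage site.
    """

    seed: int = 0
    # locus layout (genomic coordinates on the synthetic chromosome)
    orf_codons: int = 300
    utr5: int = 100
    intron: tuple[int, int] = (1060, 1210)  # (donor, acceptor), 0-based half-open
    pcpa_pos: int = 1400
    chrom_len: int = 3500
    stall_codons: tuple[str, str] = ("CCA", "GGT")  # Pro, Gly
    # ribosome footprints
    stall_pair: tuple[int, int] = (148, 149)  # 1-based codon indices
    stall_multiplier: float = 80.0
    periodicity: float = 0.8
    length_dist: dict[int, float] = field(
        default_factory=lambda: {25: 0.05, 26: 0.08, 27: 0.15, 28: 0.30,
                                 29: 0.20, 30: 0.12, 31: 0.06, 32: 0.04}
    )
    offsets_true: dict[int, int] = field(
        default_factory=lambda: {25: 10, 26: 10, 27: 11, 28: 12,
                                 29: 12, 30: 13, 31: 13, 32: 14}
    )
    n_rfp: int = 50_000
    isoform_weights: tuple[float, float] = (0.95, 0.05)  # (spliced, unspliced)
    # small RNAs
    n_srna: int = 20_000
    breakpoint_nt: int = 447  # 1-based, ORF-relative
    srna_sizes: dict[int, float] = field(
        default_factory=lambda: {21: 0.5, 22: 0.3, 24: 0.2}
    )
    srna_background: float = 0.02
    # RACE clones
    n_clones: int = 36
    clone_noise: float = 1.0 / 6.0
    clone_len_range: tuple[int, int] = (80, 200)
    # count / Ct tables
    n_count_features: int = 24
    nb_dispersion: float = 0.05
    ct_noise_sd: float = 0.2
    ct_replicates: int = 3
    copy_numbers: dict[str, float] = field(
        default_factory=lambda: {"WT": 2.0, "epi_F8": 40.0}
    )

    def __post_init__(self) -> None:
        for name, dist in (("length_dist", self.length_dist),
                           ("srna_sizes", self.srna_sizes)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if any(not 25 <= ln <= 32 for ln in self.length_dist):
            raise ValueError("footprint lengths must lie in 25-32 nt")
        if any(not 18 <= ln <= 30 for ln in self.srna_sizes):
            raise ValueError("sRNA sizes must lie in 18-30 nt")
        if abs(sum(self.isoform_weights) - 1.0) > 1e-9:
            raise ValueError("isoform_weights must sum to 1")
        i, j = self.stall_pair
        if not (1 <= i < j <= self.orf_codons and j == i + 1):
            raise ValueError("stall_pair must be consecutive codons within the ORF")
        if not 1 <= self.breakpoint_nt <= 3 * self.orf_codons:
            raise ValueError("breakpoint_nt must fall within the ORF")
        if not 1 / 3 - 1e-9 <= self.periodicity <= 1.0:
            raise ValueError("periodicity must lie in [1/3, 1]")
        if self.stall_multiplier < 1:
            raise ValueError("stall_multiplier must be >= 1")
        for ln, off in self.offsets_true.items():
            if not 0 < off < ln:
                raise ValueError(f"offset for length {ln} must lie in (0, {ln})")

    # derived coordinates -------------------------------------------------
    @property
    def cds_gstart(self) -> int:
        return self.utr5

    @property
    def cds_gend(self) -> int:
        # CDS includes the stop codon
        return self.utr5 + 3 * (self.orf_codons + 1)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), salt])


# ---------------------------------------------------------------------------
# Locus construction

def make_synthetic_locus(
    config: SimulationConfig,
) -> tuple[NamedSequence, list[TranscriptModel]]:
    """Build the two-isoform locus: one chromosome, [spliced, full-length] models.

    Layout (plus strand): 35S-like leader | GAG ORF | spacer | GT..intron..AG |
    exon2 ending at the PCPA site for the spliced isoform; the full-length
    isoform retains the intron and runs to the chromosome end.
    """
    donor, acceptor = config.intron
    if donor < config.cds_gend:
        raise ValueError("intron donor falls inside the declared ORF")
    if not (config.cds_gend <= donor < acceptor < config.pcpa_pos <= config.chrom_len):
        raise ValueError("intron/PCPA layout inconsistent with ORF and chromosome")

    rng = _rng(config, _SALT_LOCUS)
    chrom = rng.choice(_BASES, size=config.chrom_len).tolist()

    # ORF: ATG, random sense codons, the declared stall pair, stop
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=config.orf_codons - 1))
    i, j = config.stall_pair
    codons[i - 1], codons[j - 1] = config.stall_codons
    codons.append("TAA")
    orf = "".join(codons)
    chrom[config.cds_gstart : config.cds_gend] = list(orf)

    # canonical splice dinucleotides
    chrom[donor : donor + 2] = list("GT")
    chrom[acceptor - 2 : acceptor] = list("AG")
    seq = "".join(chrom)
    genome = NamedSequence("chrTE", seq)

    spliced_exons = [(0, donor), (acceptor, config.pcpa_pos)]
    spliced_seq = seq[0:donor] + seq[acceptor : config.pcpa_pos]
    spliced = TranscriptModel(
        "TE1.short", "TE1", "chrTE", "+", spliced_exons,
        cds_start=config.cds_gstart, cds_end=config.cds_gend, sequence=spliced_seq,
    )
    full = TranscriptModel(
        "TE1.full", "TE1", "chrTE", "+", [(0, config.chrom_len)],
        cds_start=config.cds_gstart, cds_end=config.cds_gend, sequence=seq,
    )
    return genome, [spliced, full]


# ---------------------------------------------------------------------------
# Ribosome footprints

def _dwell_weights(n_sense: int, pair: tuple[int, int] | None, multiplier: float) -> np.ndarray:
    w = np.ones(n_sense)
    if pair is not None and multiplier > 1:
        i, j = pair
        if j <= n_sense:
            w[i - 1] = multiplier
            w[j - 1] = multiplier
    return w / w.sum()


def _sample_footprints(
    rng: np.random.Generator,
    model: TranscriptModel,
    n: int,
    dwell: np.ndarray,
    config: SimulationConfig,
    id_prefix: str,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    lengths_avail = np.array(sorted(config.length_dist))
    length_p = np.array([config.length_dist[ln] for ln in lengths_avail])
    codon = rng.choice(len(dwell), size=n, p=dwell)  # 0-based codon index
    length = lengths_avail[rng.choice(len(lengths_avail), size=n, p=length_p)]
    offset = np.array([config.offsets_true[ln] for ln in lengths_avail])[
        np.searchsorted(lengths_avail, length)
    ]
    five = model.cds_start + 3 * codon - offset
    jitter_mask = rng.random(n) >= config.periodicity
    jitter = np.where(jitter_mask, rng.integers(1, 3, size=n), 0)
    five = five + jitter
    start = np.clip(five, 0, model.length - length)
    reads = [
        AlignedRead(f"{id_prefix}{k:06d}", model.transcript_id,
                    int(start[k]), int(length[k]), "+", 1.0)
        for k in range(n)
    ]
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "transcript_id": model.transcript_id,
            "true_codon": codon + 1,
            "length": length,
            "frame_jitter": jitter,
        }
    )
    return reads, truth


def simulate_rfp(
    config: SimulationConfig, models: Sequence[TranscriptModel]
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate ribosome footprints over the locus isoforms (transcript space).

    Each footprint picks an isoform by translation weight, a codon by dwell
    weight (uniform except the stall pair, amplified ``stall_multiplier``-fold),
    a length from ``length_dist``, places its 5' end ``offsets_true[length]``
    upstream of the codon, and is jittered into frames 1/2 with probability
    ``1 - periodicity``.
    """
    if config.n_rfp <= 0:
        raise ValueError("n_rfp must be positive")
    coding = [m for m in models if m.has_cds]
    if not coding:
        raise ValueError("no coding models supplied")
    weights = np.asarray(config.isoform_weights[: len(coding)], dtype=float)
    weights = weights / weights.sum()
    rng = _rng(config, _SALT_RFP)
    per_iso = rng.multinomial(config.n_rfp, weights)
    all_reads: list[AlignedRead] = []
    truths = []
    for m, n_m in zip(coding, per_iso):
        if n_m == 0:
            continue
        n_sense = m.n_codons - 1
        dwell = _dwell_weights(n_sense, config.stall_pair, config.stall_multiplier)
        reads, truth = _sample_footprints(
            rng, m, int(n_m), dwell, config, f"rfp_{m.transcript_id}_"
        )
        all_reads.extend(reads)
        truths.append(truth)
    return all_reads, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Small RNAs

def simulate_srna(
    config: SimulationConfig, models: Sequence[TranscriptModel]
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate double-stranded-region siRNAs confined 3' of the breakpoint.

    Signal reads fall entirely within [breakpoint, spliced 3' end) on both
    strands with equal probability; a ``srna_background`` fraction is uniform
    over the whole spliced isoform.
    """
    spliced = models[0]
    L = spliced.length
    bp_t = spliced.cds_start + config.breakpoint_nt - 1  # 0-based transcript pos
    rng = _rng(config, _SALT_SRNA)
    n = config.n_srna
    sizes_avail = np.array(sorted(config.srna_sizes))
    size_p = np.array([config.srna_sizes[s] for s in sizes_avail])
    size = sizes_avail[rng.choice(len(sizes_avail), size=n, p=size_p)]
    is_bg = rng.random(n) < config.srna_background
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    # leftmost start positions; signal reads lie fully 3' of the breakpoint
    hi_sig = L - size
    start = bp_t + np.floor(rng.random(n) * (hi_sig - bp_t + 1)).astype(int)
    start_bg = np.floor(rng.random(n) * (L - size + 1)).astype(int)
    start = np.where(is_bg, start_bg, start)
    reads = [
        AlignedRead(f"srna{k:06d}", spliced.transcript_id,
                    int(start[k]), int(size[k]), str(strand[k]), 1.0)
        for k in range(n)
    ]
    truth = pd.DataFrame(
        {"read_id": [r.read_id for r in reads], "background": is_bg, "size": size}
    )
    return reads, truth


# ---------------------------------------------------------------------------
# RACE clones

def simulate_race_clones(
    config: SimulationConfig, reference: NamedSequence | TranscriptModel
) -> tuple[list[NamedSequence], pd.DataFrame]:
    """Simulate Sanger-sequenced RACE clones of 5'OH cleavage fragments.

    A fraction ``1 - clone_noise`` of clones starts exactly at the breakpoint
    (ORF coordinate converted to the reference frame internally); the rest
    start uniformly elsewhere on the reference.
    """
    if isinstance(reference, TranscriptModel):
        seq = reference.sequence
        cds_start = reference.cds_start or 0
    else:
        seq = reference.seq
        cds_start = config.utr5
    L = len(seq)
    bp = cds_start + config.breakpoint_nt - 1  # 0-based
    lo, hi = config.clone_len_range
    rng = _rng(config, _SALT_CLONES)
    n = config.n_clones
    is_noise = rng.random(n) < config.clone_noise
    length = rng.integers(lo, hi + 1, size=n)
    start = np.full(n, bp)
    # noisy clones start uniformly at other positions with room for a clone
    noise_pos = rng.integers(0, max(1, L - lo), size=n)
    noise_pos = np.where(noise_pos == bp, (noise_pos + 1) % max(1, L - lo), noise_pos)
    start = np.where(is_noise, noise_pos, start)
    clones = []
    for k in range(n):
        s = int(start[k])
        e = min(L, s + int(length[k]))
        clones.append(NamedSequence(f"clone{k:03d}", seq[s:e]))
    truth = pd.DataFrame(
        {
            "clone_id": [c.id for c in clones],
            "true_start": start + 1,  # 1-based reference coordinate
            "is_noise": is_noise,
        }
    )
    return clones, truth


# ---------------------------------------------------------------------------
# Count and Ct tables

def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a polysome/total count table and a genomic-qPCR Ct table.

    Counts are negative-binomial around configured abundances and polysome
    enrichments (``nb_dispersion`` 0 means exact expected values).  Ct values
    are ideal Cts plus Gaussian noise of sd ``ct_noise_sd``; the EVD-like
    target amount scales with the configured copy number while the ACT2/GAPC
    references stay at one copy equivalent.
    """
    rng = _rng(config, _SALT_COUNTS)
    n = config.n_count_features
    feature_id = [f"TE{k:03d}" for k in range(n)]
    length = rng.integers(1_000, 6_000, size=n)
    base = np.exp(rng.normal(3.0, 1.0, size=n))  # arbitrary abundance units
    enrich = rng.normal(0.0, 1.0, size=n)  # true log2 polysome enrichment
    sirna = np.exp(rng.normal(0.0, 1.5, size=n))
    depth = 1e6  # nominal library depth shared by both libraries
    mu_total = base * (length / 1e3)
    mu_poly = mu_total * np.power(2.0, enrich)

    def _nb(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion <= 0:
            return mu.astype(float)
        r = 1.0 / config.nb_dispersion
        return rng.negative_binomial(r, r / (r + mu)).astype(float)

    total_count = _nb(mu_total)
    poly_count = _nb(mu_poly)
    counts = pd.DataFrame(
        {
            "feature_id": feature_id,
            "length": length,
            "total_count": total_count,
            "polysome_count": poly_count,
            "total_rpkm": total_count / (length / 1e3) / (depth / 1e6),
            "polysome_rpkm": poly_count / (length / 1e3) / (depth / 1e6),
            "sirna_level": sirna,
            "class": "TE",
            "true_log2_enrichment": enrich,
        }
    )

    base_ct = {"EVD": 26.0, "ACT2": 26.0, "GAPC": 25.0}
    rows = []
    for sample, copies in config.copy_numbers.items():
        amounts = {"EVD": float(copies), "ACT2": 1.0, "GAPC": 1.0}
        for target, amount in amounts.items():
            ideal = base_ct[target] - math.log2(amount)
            for rep in range(1, config.ct_replicates + 1):
                ct = ideal + rng.normal(0.0, config.ct_noise_sd)
                rows.append(
                    {
                        "sample": sample,
                        "target": target,
                        "replicate": rep,
                        "ct": ct,
                        "is_reference": target in ("ACT2", "GAPC"),
                    }
                )
    ct_table = pd.DataFrame(rows)
    return counts, ct_table


# ---------------------------------------------------------------------------
# Whole-transcriptome footprint simulation (for ranking/recovery studies)

def make_synthetic_transcriptome(
    config: SimulationConfig,
    n_genes: int = 200,
    orf_codon_range: tuple[int, int] = (120, 250),
    stalled_gene: int = 0,
    stalled_orf_codons: int | None = None,
) -> list[TranscriptModel]:
    """Build ``n_genes`` single-isoform coding genes, one carrying the stall.

    The stalled gene's ORF defaults to just past the stall pair scaled to the
    configured pair (>= stall codon + 12), emulating a transcript whose stall
    site sits within the ORF body.
    """
    rng = _rng(config, _SALT_TXOME)
    i, j = config.stall_pair
    if stalled_orf_codons is None:
        stalled_orf_codons = max(j + 12, orf_codon_range[0])
    models = []
    for g in range(n_genes):
        n_codons = (
            stalled_orf_codons
            if g == stalled_gene
            else int(rng.integers(orf_codon_range[0], orf_codon_range[1] + 1))
        )
        utr5, utr3 = 30, 30
        codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=n_codons - 1)) + ["TAA"]
        if g == stalled_gene:
            codons[i - 1], codons[j - 1] = config.stall_codons
        seq = (
            "".join(rng.choice(_BASES, size=utr5))
            + "".join(codons)
            + "".join(rng.choice(_BASES, size=utr3))
        )
        models.append(
            TranscriptModel(
                f"g{g:04d}.1", f"g{g:04d}", f"chr_g{g:04d}", "+",
                [(0, len(seq))],
                cds_start=utr5, cds_end=utr5 + 3 * (n_codons + 1), sequence=seq,
            )
        )
    return models


def simulate_transcriptome_rfp(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    stalled_gene: int = 0,
    expression_sd: float = 0.5,
    stalled_expression_factor: float = 3.0,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Distribute ``n_rfp`` footprints over a transcriptome.

    Expression weights are lognormal across genes; the stalled transcript is
    overexpressed ``stalled_expression_factor``-fold over the mean weight,
    mirroring a strong-promoter transgene.  Only the stalled transcript's
    dwell weights carry the stall pair.
    """
    rng = _rng(config, _SALT_TXOME + 100)
    n_genes = len(models)
    w = np.exp(rng.normal(0.0, expression_sd, size=n_genes))
    w[stalled_gene] = stalled_expression_factor * w.mean()
    w = w / w.sum()
    per_gene = rng.multinomial(config.n_rfp, w)
    all_reads: list[AlignedRead] = []
    truths = []
    for g, (m, n_m) in enumerate(zip(models, per_gene)):
        if n_m == 0:
            continue
        pair = config.stall_pair if g == stalled_gene else None
        dwell = _dwell_weights(m.n_codons - 1, pair, config.stall_multiplier)
        reads, truth = _sample_footprints(
            rng, m, int(n_m), dwell, config, f"rfp_{m.transcript_id}_"
        )
        all_reads.extend(reads)
        truths.append(truth)
    return all_reads, pd.concat(truths, ignore_index=True)
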