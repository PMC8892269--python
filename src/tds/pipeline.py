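"""End-to-end orchestration: simulate -> P-sites -> stalling -> siRNA -> overlay.

``run_pipeline`` drives every stage on a synthetic locus and reports how the
three independent signals line up: the maximal ribosome stall, the 5' onset of
the siRNA pattern, and the modal 5'OH breakage end.  All positions in the
overlay are 1-based ORF-relative nucleotides; the stall is placed at the 3'
nucleotide of its maximal codon (codon c -> nt 3c).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tds import psite, raceends, srna_profiles, stalling, synthio
from tds.ioformats import (
    CoverageTrack,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_tabular_alignments,
)

__all__ = ["OverlayReport", "run_pipeline"]

logger = logging.getLogger(__name__)


def _version() -> str:
    import tds
    return tds.__version__


@dataclass
class OverlayReport:
    """Alignment of the stall site, siRNA onset and modal 5'OH end (ORF nt)."""

    locus: str
    max_codon: int
    stall_pair: tuple[int, int]
    pair_fraction: float
    max_score: float
    percentile: float | None
    stall_nt: int  # 3' nt of the maximal codon, 1-based ORF-relative
    onset_nt: int | None  # 1-based ORF-relative, None when no step detected
    modal_end_nt: int | None  # 1-based ORF-relative
    modal_end_count: int
    modal_end_fraction: float
    qualified: bool

    @property
    def distance_stall_onset(self) -> int | None:
        if self.onset_nt is None:
            return None
        return abs(self.stall_nt - self.onset_nt)

    @property
    def distance_stall_modal_end(self) -> int | None:
        if self.modal_end_nt is None:
            return None
        return abs(self.stall_nt - self.modal_end_nt)

    @property
    def distance_onset_modal_end(self) -> int | None:
        if self.onset_nt is None or self.modal_end_nt is None:
            return None
        return abs(self.onset_nt - self.modal_end_nt)

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["stall_pair"] = f"{self.stall_pair[0]}-{self.stall_pair[1]}"
        d["distance_stall_onset"] = self.distance_stall_onset
        d["distance_stall_modal_end"] = self.distance_stall_modal_end
        d["distance_onset_modal_end"] = self.distance_onset_modal_end
        return pd.DataFrame([d])


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: synthio.SimulationConfig,
    outdir: str | Path | None = None,
    min_support: float = 50,
) -> OverlayReport:
    """Run every stage on the synthetic locus and overlay the three signals.

    When ``outdir`` is given, every intermediate artifact (FASTA, GFF3,
    tabular alignments, offset/occupancy/stall tables, bedGraph tracks, the
    overlay table and a JSON run log) is written there.

    ``min_support`` defaults below the transcriptome-scale threshold of 100
    because a single-locus run pools start-codon metagene evidence from just
    one start; read lengths still below it are dropped, not guessed.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    genome, models = synthio.make_synthetic_locus(config)
    spliced = models[0]
    rfp_reads, rfp_truth = synthio.simulate_rfp(config, models)
    srna_reads, srna_truth = synthio.simulate_srna(config, models)
    clones, clone_truth = synthio.simulate_race_clones(config, spliced)
    counts, ct_table = synthio.simulate_counts(config)

    # --- ribosome profiling ----------------------------------------------
    offsets = psite.estimate_offsets(rfp_reads, models, min_support=min_support)
    occupancies = psite.assign_psites(rfp_reads, offsets, models)
    frames, metagene = psite.periodicity_qc(rfp_reads, offsets, models)
    qualified, excluded = stalling.select_isoforms(occupancies, models)
    reports = [stalling.stall_scores(occ) for occ in occupancies.values()]
    qualified_reports = [r for r in reports if r.transcript_id in qualified]
    if qualified_reports:
        stalling.rank_transcripts(qualified_reports)
    report_by_id = {r.transcript_id: r for r in reports}
    stall = report_by_id[spliced.transcript_id]

    # --- small RNAs -------------------------------------------------------
    profile = srna_profiles.size_profile(
        srna_reads, spliced.transcript_id, spliced.length,
        library_total=max(config.n_srna, 1),  # empty library -> zero track
    )
    onset_t = srna_profiles.onset_changepoint(profile)  # 1-based transcript nt
    onset_nt = None if onset_t is None else onset_t - spliced.cds_start

    # --- 5'OH ends --------------------------------------------------------
    clone_ends = raceends.map_clone_5p(clones, spliced.sequence)
    (modal_lo, modal_hi), modal_count, modal_frac = raceends.modal_end_fraction(clone_ends)
    # report the most frequent single position within the modal window
    mapped = [e.end5 for e in clone_ends if e.mapped and modal_lo <= e.end5 <= modal_hi]
    modal_end_t = max(sorted(set(mapped)), key=mapped.count) if mapped else None
    modal_end_nt = None if modal_end_t is None else modal_end_t - spliced.cds_start

    overlay = OverlayReport(
        locus=spliced.transcript_id,
        max_codon=stall.max_codon,
        stall_pair=stall.pair,
        pair_fraction=stall.pair_fraction,
        max_score=stall.max_score,
        percentile=stall.percentile,
        stall_nt=3 * stall.max_codon,
        onset_nt=onset_nt,
        modal_end_nt=modal_end_nt,
        modal_end_count=modal_count,
        modal_end_fraction=modal_frac,
        qualified=spliced.transcript_id in qualified,
    )

    if out is not None:
        _write_artifacts(
            out, config, genome, models, rfp_reads, srna_reads, clones,
            offsets, occupancies, reports, frames, profile, clone_ends,
            counts, ct_table, overlay,
        )
    return overlay


def _write_artifacts(
    out: Path, config, genome, models, rfp_reads, srna_reads, clones,
    offsets, occupancies, reports, frames, profile, clone_ends,
    counts, ct_table, overlay,
) -> None:
    spliced = models[0]
    write_fasta([genome], out / "genome.fa")
    write_gff3(models, out / "models.gff3")
    write_fasta(clones, out / "clones.fa")
    write_tabular_alignments(rfp_reads, out / "rfp.tab")
    write_tabular_alignments(srna_reads, out / "srna.tab")
    pd.DataFrame(
        [{"length": ln, "offset": off, "support": offsets.support[ln]}
         for ln, off in sorted(offsets.offsets.items())]
    ).to_csv(out / "offsets.tsv", sep="\t", index=False)
    occ_rows = [
        {"transcript_id": tid, "codon": k + 1, "count": c}
        for tid, occ in occupancies.items()
        for k, c in enumerate(occ.counts)
    ]
    pd.DataFrame(occ_rows).to_csv(out / "occupancy.tsv", sep="\t", index=False)
    stalling.reports_to_frame(reports).to_csv(out / "stall_report.tsv", sep="\t", index=False)
    frames.to_csv(out / "periodicity.tsv", sep="\t", index=False)
    for track in profile.to_tracks():
        write_bedgraph(track, out / f"{track.label}.bedgraph")
    pd.DataFrame(
        [{"clone_id": e.clone_id, "mapped": e.mapped, "end5": e.end5,
          "mismatches": e.mismatches} for e in clone_ends]
    ).to_csv(out / "clone_ends.tsv", sep="\t", index=False)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    ct_table.to_csv(out / "ct_values.tsv", sep="\t", index=False)
    overlay.to_frame().to_csv(out / "overlay.tsv", sep="\t", index=False)
    log = {
        "tds_version": _version(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "input_checksums": {
            p.name: _sha1(p)
            for p in [out / "genome.fa", out / "models.gff3",
                      out / "rfp.tab", out / "srna.tab", out / "clones.fa"]
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
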