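"""Stalling scores, qualification filters, percentiles and codon statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tds import psite, stalling, synthio
from tds.ioformats import TranscriptModel
from tds.psite import CodonOccupancy


def _occ(counts, tid="t"):
    return CodonOccupancy(tid, np.asarray(counts, dtype=float))


def _brute_force_stall(counts):
    """Independent recomputation: observed/expected scores, max, pair fraction."""
    counts = list(counts)
    n, total = len(counts), sum(counts)
    mean = total / n
    scores = [c / mean for c in counts]
    max_idx = scores.index(max(scores))
    best_pair, best_sum = None, -1.0
    for i in range(n - 2):  # last sense codon excluded from the pair search
        s = counts[i] + counts[i + 1]
        if s > best_sum:
            best_pair, best_sum = (i + 1, i + 2), s
    return scores, max_idx + 1, best_pair, best_sum / total


# ---------------------------------------------------------------------------
# stall_scores

def test_uniform_counts_score_one_everywhere():
    r = stalling.stall_scores(_occ([4.0] * 10))
    np.testing.assert_allclose(r.scores, 1.0)
    assert r.pair_fraction == pytest.approx(0.2)


def test_single_spike_arithmetic():
    r = stalling.stall_scores(_occ([1, 1, 1, 1, 16, 1, 1, 1, 1, 1]))
    assert r.max_score == pytest.approx(16 / 2.5)  # mean 2.5 -> score 6.4
    assert r.max_codon == 5
    assert r.pair in ((4, 5), (5, 6))
    assert r.pair_fraction == pytest.approx(17 / 25)


def test_zero_total_not_qualified():
    r = stalling.stall_scores(_occ([0.0] * 5))
    assert not r.qualified and r.reason == "no_reads"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 100), min_size=3, max_size=400))
def test_stall_scores_matches_brute_force(counts):
    if sum(counts) <= 0:
        return
    r = stalling.stall_scores(_occ(counts))
    scores, max_codon, pair, pair_fraction = _brute_force_stall(counts)
    np.testing.assert_allclose(r.scores, scores, rtol=1e-12)
    assert abs(np.mean(r.scores) - 1.0) < 1e-9
    assert r.max_score == pytest.approx(max(scores))
    assert r.pair_fraction == pytest.approx(pair_fraction)


# ---------------------------------------------------------------------------
# select_isoforms

def _model(tid, gene, n_codons=10):
    seq = "ATG" + "GCT" * (n_codons - 1) + "TAA"
    return TranscriptModel(tid, gene, "c", "+", [(0, len(seq))],
                           cds_start=0, cds_end=len(seq), sequence=seq)


def test_select_isoforms_filters():
    models = [_model("a.1", "a"), _model("a.2", "a"), _model("b.1", "b")]
    occ = {
        "a.1": _occ([10] * 10, "a.1"),          # most translated, full coverage
        "a.2": _occ([4] * 10, "a.2"),           # minor isoform
        "b.1": _occ([1] * 6 + [0] * 4, "b.1"),  # 60% coverage
    }
    kept, excluded = stalling.select_isoforms(occ, models)
    assert set(kept) == {"a.1"}
    assert excluded == {"a.2": "not_most_translated", "b.1": "coverage"}


def test_select_isoforms_boundary_70_percent_included():
    models = [_model("a.1", "a")]
    occ = {"a.1": _occ([1] * 7 + [0] * 3, "a.1")}  # exactly 0.70
    kept, _ = stalling.select_isoforms(occ, models)
    assert "a.1" in kept


# ---------------------------------------------------------------------------
# rank_transcripts

def _report(tid, max_score):
    r = stalling.StallReport(tid, np.array([max_score]), max_score=max_score, max_codon=1)
    return r


def test_percentile_counting():
    reports = [_report(t, s) for t, s in {"A": 6.4, "B": 2.0, "C": 1.5, "D": 9.9}.items()]
    pct = stalling.rank_transcripts(reports)
    assert pct["A"] == 25.0
    assert pct["D"] == 0.0
    assert pct["C"] == 75.0


def test_percentile_single_and_ties():
    assert stalling.rank_transcripts([_report("x", 5.0)])["x"] == 0.0
    pct = stalling.rank_transcripts([_report("A", 5.0), _report("B", 5.0), _report("C", 1.0)])
    assert pct["A"] == 0.0 and pct["B"] == 0.0  # strict inequality
    assert pct["C"] == pytest.approx(100 * 2 / 3)


def test_percentile_monotone_under_score_decrease():
    rng = np.random.default_rng(0)
    scores = rng.uniform(1, 10, size=30)
    reports = [_report(f"t{i}", s) for i, s in enumerate(scores)]
    pct = stalling.rank_transcripts(reports)
    lowered = [_report(f"t{i}", s if i != 7 else s / 2) for i, s in enumerate(scores)]
    pct2 = stalling.rank_transcripts(lowered)
    assert pct2["t7"] >= pct["t7"]


def test_rank_empty_errors():
    with pytest.raises(ValueError, match="empty qualified"):
        stalling.rank_transcripts([])


# ---------------------------------------------------------------------------
# dwell_and_usage

def test_dwell_uniform_occupancy_and_no_stops():
    models = [_model("a.1", "a"), _model("b.1", "b")]
    occ = {
        "a.1": _occ([2.0] * 10, "a.1"),
        "b.1": _occ([5.0] * 10, "b.1"),
    }
    stats = stalling.dwell_and_usage(occ, models)
    vals = set(round(v, 12) for v in stats.dwell.values())
    assert len(vals) == 1  # uniform occupancy -> equal dwell everywhere
    assert all(c not in stats.dwell for c in ("TAA", "TAG", "TGA"))
    assert all(c not in stats.usage for c in ("TAA", "TAG", "TGA"))
    assert sum(stats.usage.values()) == pytest.approx(1.0)


def test_dwell_recovers_slow_codon():
    # one codon dwell-amplified 5x in a simulated transcriptome
    cfg = synthio.SimulationConfig(seed=21, periodicity=1.0, n_rfp=40_000,
                                   length_dist={28: 1.0}, offsets_true={28: 12})
    models = synthio.make_synthetic_transcriptome(cfg, n_genes=40)
    # amplify every occurrence of CTG by resampling truth counts
    reads, truth = synthio.simulate_transcriptome_rfp(cfg, models)
    offsets = psite.estimate_offsets(reads, models, min_support=100)
    occ = psite.assign_psites(reads, offsets, models)
    slow = "CTG"
    for tid, o in occ.items():
        m = next(mm for mm in models if mm.transcript_id == tid)
        cds = m.cds_sequence
        for k in range(o.n_codons):
            if cds[3 * k : 3 * k + 3] == slow:
                o.counts[k] *= 5
    stats = stalling.dwell_and_usage(occ, models)
    assert max(stats.dwell, key=stats.dwell.get) == slow
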