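"""Determinism, construction and sampling-distribution checks of the simulators."""

import numpy as np
import pytest
from scipy import stats

from tds import synthio
from tds.seqscan import GENETIC_CODE


def test_locus_deterministic_under_seed(default_config):
    g1, m1 = synthio.make_synthetic_locus(default_config)
    g2, m2 = synthio.make_synthetic_locus(default_config)
    assert g1 == g2
    assert [m.sequence for m in m1] == [m.sequence for m in m2]


def test_spliced_isoform_is_exon1_plus_exon2_up_to_pcpa(default_config, locus):
    genome, (spliced, full) = locus
    donor, acceptor = default_config.intron
    expected = genome.seq[:donor] + genome.seq[acceptor : default_config.pcpa_pos]
    assert spliced.sequence == expected
    assert full.sequence == genome.seq


def test_declared_orf_translates_without_internal_stop(default_config, locus):
    _, (spliced, _) = locus
    cds = spliced.cds_sequence
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    assert codons[0] == "ATG"
    aa = [GENETIC_CODE[c] for c in codons]
    assert aa[-1] == "*" and "*" not in aa[:-1]
    # the declared stall pair codes for proline-glycine
    i, j = default_config.stall_pair
    assert (aa[i - 1], aa[j - 1]) == ("P", "G")


def test_inconsistent_intron_errors():
    with pytest.raises(ValueError, match="intron"):
        synthio.make_synthetic_locus(
            synthio.SimulationConfig(intron=(500, 700))  # donor inside the ORF
        )


def test_rfp_uniform_null_is_multinomially_flat(locus):
    cfg = synthio.SimulationConfig(seed=3, stall_multiplier=1.0, periodicity=1.0,
                                   n_rfp=30_000, isoform_weights=(1.0, 0.0))
    reads, truth = synthio.simulate_rfp(cfg, locus[1])
    counts = truth["true_codon"].value_counts().reindex(range(1, cfg.orf_codons + 1), fill_value=0)
    chi2 = stats.chisquare(counts)
    assert chi2.pvalue > 0.001  # uniform within multinomial error


def test_rfp_stall_recovery_in_truth_table(locus, default_config):
    cfg = synthio.SimulationConfig(seed=4, stall_multiplier=20.0, n_rfp=50_000)
    reads, truth = synthio.simulate_rfp(cfg, locus[1])
    top = truth["true_codon"].value_counts().idxmax()
    assert top in cfg.stall_pair


def test_rfp_length_histogram_matches_distribution(locus):
    cfg = synthio.SimulationConfig(seed=5, n_rfp=10_000)
    _, truth = synthio.simulate_rfp(cfg, locus[1])
    obs = truth["length"].value_counts().reindex(sorted(cfg.length_dist), fill_value=0)
    exp = np.array([cfg.length_dist[ln] for ln in sorted(cfg.length_dist)]) * len(truth)
    assert stats.chisquare(obs, exp).pvalue > 0.01


def test_rfp_rejects_nonpositive_counts(locus):
    with pytest.raises(ValueError, match="n_rfp"):
        synthio.simulate_rfp(synthio.SimulationConfig(n_rfp=0), locus[1])


def test_srna_confined_3prime_of_breakpoint_without_background(locus, default_config):
    cfg = synthio.SimulationConfig(seed=6, srna_background=0.0)
    reads, _ = synthio.simulate_srna(cfg, locus[1])
    bp_t = locus[1][0].cds_start + cfg.breakpoint_nt - 1
    assert all(r.start >= bp_t for r in reads)  # both strands


def test_srna_size_fractions_match_configuration(locus):
    cfg = synthio.SimulationConfig(seed=7, n_srna=20_000)
    _, truth = synthio.simulate_srna(cfg, locus[1])
    frac = truth["size"].value_counts(normalize=True)
    for size, p in cfg.srna_sizes.items():
        assert frac[size] == pytest.approx(p, abs=0.02)


def test_srna_deterministic(locus, default_config):
    r1, _ = synthio.simulate_srna(default_config, locus[1])
    r2, _ = synthio.simulate_srna(default_config, locus[1])
    assert r1 == r2


def test_race_clones_match_reference_at_breakpoint(locus, default_config):
    cfg = synthio.SimulationConfig(seed=8, clone_noise=0.0)
    spliced = locus[1][0]
    clones, truth = synthio.simulate_race_clones(cfg, spliced)
    bp0 = spliced.cds_start + cfg.breakpoint_nt - 1
    assert all(c.seq[:25] == spliced.sequence[bp0 : bp0 + 25] for c in clones)
    assert truth["is_noise"].sum() == 0


def test_race_clone_noise_binomial_expectation(locus):
    # design point: 36 clones, noise 1/6 -> 30 modal clones expected
    n_modal = []
    for seed in range(60):
        cfg = synthio.SimulationConfig(seed=seed)
        _, truth = synthio.simulate_race_clones(cfg, locus[1][0])
        n_modal.append((~truth["is_noise"]).sum())
    sd = np.sqrt(36 * (5 / 6) * (1 / 6) / 60)
    assert np.mean(n_modal) == pytest.approx(30, abs=3 * sd)


def test_race_deterministic(locus, default_config):
    c1, _ = synthio.simulate_race_clones(default_config, locus[1][0])
    c2, _ = synthio.simulate_race_clones(default_config, locus[1][0])
    assert c1 == c2


def test_counts_zero_noise_recovers_enrichment_exactly():
    cfg = synthio.SimulationConfig(seed=9, nb_dispersion=0.0)
    counts, _ = synthio.simulate_counts(cfg)
    obs = np.log2(counts["polysome_rpkm"] / counts["total_rpkm"])
    np.testing.assert_allclose(obs, counts["true_log2_enrichment"], atol=1e-9)


def test_counts_deterministic(default_config):
    c1, t1 = synthio.simulate_counts(default_config)
    c2, t2 = synthio.simulate_counts(default_config)
    assert c1.equals(c2) and t1.equals(t2)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="sum to 1"):
        synthio.SimulationConfig(srna_sizes={21: 0.5, 22: 0.2})
    with pytest.raises(ValueError, match="stall_pair"):
        synthio.SimulationConfig(stall_pair=(299, 300), orf_codons=200)
    with pytest.raises(ValueError, match="breakpoint"):
        synthio.SimulationConfig(breakpoint_nt=5000)
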