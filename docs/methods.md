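# Methods

`tds` implements the computational core of a translation-dependent silencing
analysis: locating discrete ribosome stalling events on heavily translated
mRNAs, profiling the size classes of the small interfering RNAs those mRNAs
spawn, tallying the 5' ends of 5'-hydroxyl (5'OH) cleavage fragments, and
overlaying the three signals in one coordinate system. A synthetic-data
generator emulates the biological system — a reactivated *Ty1/Copia*-like
retroelement whose spliced, PCPA-shortened GAG isoform is translated almost
exclusively, stalls intensely on one codon pair, and spawns RDR6-dependent
siRNAs strictly 3' of a breakage point inside its ORF — so every stage is
testable without sequencing downloads.

## Ribosome profiling model

**Offsets.** Footprints of length L (25–32 nt) protect the ribosome's P-site
at a length-dependent distance d(L) from their 5' end. d(L) is estimated from
the 5'-end profile around annotated start codons: for each L, candidate
distances d ∈ [6, L−6] are scored by the weighted count of reads whose 5' end
lies d nt upstream of a start. Under uniform elongation the counts at d_true,
d_true−3, d_true−6 … are equal in expectation (codons 1, 2, 3 …), while
nothing maps upstream of the start; the offset is therefore the **largest**
candidate whose count reaches half the maximum — the upstream edge of
coverage. This is exact on noiseless simulations and robust to frame jitter.
Lengths with fewer than `min_support` start-proximal reads (default 100;
lowered to 50 in single-locus runs, where only one start contributes) are
dropped, never guessed.

**Occupancy and stalling score.** P-site nt = 5' end + d(L); all three frames
pool into the codon the P-site falls in. The occupancy vector covers sense
codons only (the stop codon is excluded throughout). The stalling score at
codon c is count_c / mean(counts), so mean(score) = 1 by construction; the
strongest di-codon is searched over adjacent sense pairs excluding the last
sense codon (no stop-containing di-codons), and its `pair_fraction` is the
pair's share of the transcript total. Transcripts qualify if they are the most
translated isoform of their gene and ≥ 70% of their sense codons carry signal
("coverage" counted in codons — the spec of the upstream filter leaves
codons-vs-nucleotides open; codons match the occupancy unit). The percentile
of a stall is the percentage of qualified transcripts with a **strictly**
larger maximal score, so the most extreme transcript scores 0.

**Dwell and usage.** Dwell time of a codon is the mean of
ln((count + 0.5)/mean) over all its occurrences in qualified transcripts — a
half-read pseudo-count inside the log, chosen because the source analysis says
only "log-normalized". Usage is the codon frequency over qualified CDSs (61
sense codons, summing to 1).

## siRNA profiles and onset

Coverage profiles are browser-style: each read adds weight × 1e6/library_total
RPM to every position it covers, stratified by size class {21, 22, 24, other}
(DCL4/DCL2/DCL3 products) and strand. The **onset** of a pattern — "where the
siRNAs begin" — is found on the pooled 21+22-nt **read-start histogram**, not
on coverage: coverage is the start step convolved with the read length and
biases any step fit by ~ℓ/2 ≈ 10 nt, whereas starts form a true step at the
5' boundary. A single change-point, two-level piecewise-constant model is
fitted by least squares over all breakpoints and accepted when it removes
> 25% of the flat model's squared error (configurable); otherwise no onset is
reported. On the stated recovery world (breakpoint 441, 2% background, 20,000
reads) the estimator's median error is 0–1 nt over 50 seeds.

## 5'OH clone mapping

Clones are anchored by their first 25 bases (configurable) on the reference
with ≤ 1 mismatch; ambiguous or absent anchors leave the clone unmapped —
deliberately conservative, like screening Sanger clones by eye. The modal
breakage interval is the w-nt window (default 2, matching a two-position
breakage site) holding the most mapped 5' ends, leftmost on ties. Nucleotide
to codon conversion is codon = ceil(nt/3). Note the source system's printed
coordinates carry a one-codon tension (breakage nt 447–448 vs stall pair
148–149; nt 448 falls in codon 150): the overlay therefore reports both
nucleotide and codon coordinates and never hard-codes a reconciliation; the
stall's nucleotide coordinate is the 3' nt of its maximal codon (codon c → nt
3c).

## Abundance and qPCR

Polysome association score = log2((polysome RPKM + q)/(total RPKM + q)).
siRNA-level quartiles use the empirical 25/50/75 percentiles with ties sharing
a quartile (a fully degenerate key yields quartile 1 everywhere, with a
warning). qPCR arithmetic assumes perfect doubling (efficiency 2,
configurable): relative expression = 2^(mean ref Ct − mean target Ct) with
replicates averaged and multiple references averaged on the Ct scale; copy
number = 2 × 2^(ΔCt(s) − ΔCt(calibrator)) against a calibrator carrying two
target copies per haploid genome. Both are invariant to per-sample instrument
offsets.

## Sequence scans

CAI uses relative adaptiveness w = f/max(f) within each synonymous family
(reference usage is always an input table, e.g. from `dwell_and_usage`);
Met/Trp/stops are excluded from the geometric mean and unobserved codons floor
at w = 0.01. G-quadruplex scoring is G4Hunter-style (runs of G score
+min(run,4) per base, C runs negative, windowed mean, default window 25 and
threshold 1.2 — the source names no scorer, so a transparent published-style
default was chosen). GC/GC3 are centred, end-truncated sliding means per
codon. The longest-ORF ratio scans ATG→stop in all six frames, stop included.

## What the generator does and does not emulate

It emulates: the two-isoform layout (shared 5' exon, intron, PCPA), skewed
isoform translation, 25–32-nt footprints with 3-nt periodicity and
length-dependent offsets, a programmable dwell-factor stall, size-classed
siRNAs confined 3' of a breakpoint on both strands with uniform background,
RACE clones starting at the breakage site with a noise fraction, and
NB-count / Gaussian-Ct tables with configured effect sizes. It does **not**
emulate sequencing errors, quality scores, PCR duplicates, ribosome queuing
upstream of the stall, initiation/termination peaks, phasing of siRNAs, or
reference-genome mapping artifacts. A green recovery test therefore
establishes correctness of the estimators under the stated statistical
structure, not robustness to every artifact of real libraries.

Default effect sizes are the stated world of the emulated system: stall dwell
factor 80 on the Pro-Gly pair (148,149) puts ~35% of footprints on the pair in
a 300-codon ORF, matching the observed two-codon share; breakpoint ORF nt 447;
36 clones with noise 1/6 (30/36 modal); copy numbers {2, 40}; Ct noise sd 0.2
with 3 replicates; siRNA background 2%.

## Numerical choices

Scores and fractions are plain ratios (no shrinkage); change-point SSE uses
prefix sums (O(n) per locus); percentiles use strict inequality; offset
tie-handling is the 50%-of-max upstream rule; all RNGs are
`numpy.random.default_rng([seed, salt])` with a distinct salt per simulator so
reruns are byte-identical and streams are independent. Degenerate inputs
(zero-count transcripts, empty siRNA libraries, all-equal quartile keys,
Met/Trp-only CDSs) return flagged results or raise named errors rather than
NaN.

## Known limitations

Single change-point only (a pattern with two onsets reports the dominant one);
anchor mapping is Hamming-based (no indels); SAM support is the M/N subset
without clipping arithmetic beyond leading/trailing soft clips; the 70%
coverage filter and the offset support threshold are heuristics inherited from
the upstream analysis conventions, not estimated from data.
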