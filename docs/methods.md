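# Methods

## Scope and model

`parascreen` analyzes deep-sequencing data of phage-display peptide
libraries to identify clones whose abundance grows under amplification in
bacteria ("parasites"), and ships a generative model of the whole
experiment so that every analysis stage can be validated against known
ground truth. The library is an NNK-encoded 7-mer library: each codon has
any base at positions 1–2 and G/T at position 3, giving 32 codons, all 20
amino acids, and a single reachable stop (amber, TAG), which the
amber-suppressor host reads as glutamine. Translation therefore maps
TAG → Q and can never emit a stop symbol; the peptide alphabet is exactly
20 letters and the theoretical diversity of the 7-mer library is
20⁷ = 1.28 × 10⁹.

## Synthetic-data generator

The generator defines the study conditions; its defaults are the measured
properties of the runs the analysis is designed for, not free dials.

**Naive library.** `build_naive_population` draws clone abundances
log-normal with log-sd `skew_sd` (default 1.5) and normalizes. The true
abundance law of a manufactured library is unknown; log-normal is a
modelling choice, made once, that reproduces the qualitative shape seen in
real runs — a heavy singleton fraction together with clones thousands of
copies above uniform expectation at a 4 × 10⁶-read depth. Growth factors
are log-normal centred on 1 with log-sd `growth_sd` (default 0.1, narrow:
most clones amplify similarly). A fraction `parasite_fraction` (default
0.001) of clones is flagged parasitic and has its growth factor multiplied
by `parasite_advantage` (default 10, the low end of the 10–100-fold
enrichment observed for real parasites after one full amplification).

**Amplification.** One `round` is one full amplification of the culture
(≈10⁶-fold titer growth). Bulk mode multiplies abundance by
growth_factor^rounds and renormalizes — clones compete, and a clone's
enrichment ratio after one round equals its relative growth advantage.
Emulsion mode models one clone per droplet grown to droplet capacity:
growth factors are ignored and abundances are preserved up to a single
multiplicative loading-noise term (1 + ε), ε ~ N(0, `loading_noise_cv`)
truncated above −1 (default cv 0.2). Droplet occupancy statistics are not
simulated; loading noise is the one noise knob. No new mutants arise
during amplification.

**Read sampling.** `sample_counts` with dispersion factor φ = 1 draws a
multinomial (per-clone Poisson conditioned on the exact read total); with
φ > 1 each clone's count is negative binomial with variance φ × mean
(shape m/(φ−1), success probability 1/φ). φ ≈ 1.25 reproduces
technical-replicate and φ ≈ 1.5 biological-replicate overdispersion.

**FASTQ emission.** Reads are `barcode + flank5 + 21-nt variable + flank3`
with Phred+33 qualities; a configurable fraction (`fr_split`, default 0.5)
is emitted forward, the rest reverse-complemented. Per read,
independently: the barcode receives one substitution with probability
`barcode_error_rate` (default 0.02 — barcodes ship with pairwise Hamming
distance ≥ 3, so a corrupted barcode is never rescued); all
variable-region bases exceed the quality cut with probability
`phred_pass_rate` (default 0.60), otherwise one random variable base is
assigned a quality ≤ cut; one random codon's third position is set to A/C
with probability `nnk_violation_rate` (default 0.20); one random
substitution lands anywhere in the variable region with probability
`point_mutation_rate` (default 0.01, the order of platform error rates).
Default flanks and barcodes are arbitrary fixed strings, all
config-overridable. For a peptide multiset input, each peptide receives
one seeded random NNK back-translation per call (one clone DNA per
peptide).

What the generator does **not** emulate: indels and homopolymer errors,
quality-dependent miscalls (quality values and substitutions are
independent), chimeric reads, target-binding selection, and within-run
clone evolution. Passing tests therefore demonstrate correctness of the
analysis under this error model, not robustness to every artifact of real
platforms.

## Read processing

Exact barcode match at the read start (either strand) assigns reads to
samples; there is no mismatch rescue, matching the observed ~98% mappable
fraction. The constant flanks are located by string search, preferring the
occurrence of flank3 at exactly the expected offset so that a chance
recurrence of flank bytes inside the variable region does not truncate the
read; an enclosed segment of the wrong length is rejected. The quality
filter is strict (> 30: Q31 passes, Q30 fails), applied to the variable
region; the NNK filter requires G/T at every third codon position. Both
filters are independent predicates, so their order does not change the
accepted set; the cascade is ordered quality → NNK so that the reported
pass rates compose the way the run summaries quote them (quality among
mapped, NNK among quality-passing). F and R multisets are combined by the
per-peptide max rule; the combined total_reads is max(total_F, total_R),
the scale consistent with max-rule counts. Amber translation is
configurable in principle by filtering Q-containing peptides downstream;
the default TAG → Q matches the suppressor host.

## Error model

Point-mutant (MUT) tagging reconstructs a greedy parent-first scan:
sequences in descending count order; any unflagged sequence within
`max_distance` (default 1) of an unflagged parent and at most
`max_child_fraction` (default 0.05, from the observed 1–5% parent
fraction) of the parent's count is flagged with that parent, and flagged
sequences are never themselves parents. Removal drops flagged counts
(no merging into parents — "removed" is taken literally) and shrinks
total_reads accordingly. NNM errors are by definition non-NNK reads,
already removed by the read filter; the processing-variant labels
(F∪R/F∩R × MUT±, NNM−) only record provenance. The Hamming profile
reports each sequence's distance to its nearest higher-ranked neighbour
(rank: count descending, ties lexicographic, so all-singleton libraries
still report equal-count neighbour distances). Note that for a library of
~10³ unrelated random 7-mers the nearest-neighbour profile concentrates at
distances 3–4 simply because minima over ~10³ comparisons are small; it is
the *all-pairs* distance distribution that is dominated by distances 5–7,
and the diagnostic signature of MUT contamination is specifically the
excess at distance 1.

## Statistics

**Sampling theory.** Reads subsampled from a diversity-D library are
per-sequence Poisson with λ = n_reads/D; the package reports conditional
copy-number probabilities P(X = c | X ≥ 1) and tail expectations
D · P(X > c). For 4 × 10⁶ reads over 10⁹ clones, λ = 0.004 and fewer than
one sequence is expected above copy number 3 — which is why observed
high-copy sequences indicate library skew rather than sampling.

**Ratios and thresholds.** The normalized ratio is
(a/Nₐ)/(n/Nₙ) with a 0.5 pseudo-count added to both raw counts only when
either is zero (exact ratios are never perturbed). P₁₀/P₁ᵣ use strict
inequalities (n > 10, ratio > 3); the 3-fold cut corresponds to the 99th
percentile of ratio variation between replicate amplifications.

**Volcano (P_BR).** Counts scaled by replicate totals, missing sequences
as 0, fold fᵢ = ⟨amp⟩/⟨naive⟩ with the 0.5-read pseudo-scale only for a
zero naive mean, and a one-sided Welch t (amplified > naive) computed
directly (means, ddof-1 variances floored at 1e-12, Satterthwaite df) —
the floor handles all-zero groups, which scipy's t-test does not expose.
Deliberately no multiple-testing correction; calibration is checked by
type-I-error simulation instead.

**Overdispersion.** Scale factors s_k = total_k/mean(totals), rate
λ̂ᵢ = Σ_k N_ik / Σ_k s_k, statistic Xᵢ = Σ_k (N_ik − s_k λ̂ᵢ)²/(s_k λ̂ᵢ),
approximately χ²(k−1) under Poisson sampling. The QQ slope is fitted
through the origin over the central 10–90% quantiles (configurable)
because tail dispersion is not constant across counts; variance inflation
by φ multiplies the slope by φ (the slope is exactly scale-equivariant).

**TMM.** The published trimmed-mean-of-M-values procedure: reference
replicate by upper-quartile proximity to the mean; per-sequence M (log2
ratio) and A (mean log2 abundance) over sequences nonzero in both; double
trim (30% of M, 5% of A, both tails, average ranks for ties);
precision-weighted mean of the kept M with the standard binomial variance
weights; factors rescaled to multiply to 1. The implementation is
cross-checked in the tests against frozen `edgeR::calcNormFactors` outputs
and agrees to 6 decimals on the fixture matrices.

**NB exact test (P_ER).** A deliberately simplified exact-test pipeline —
no numerical parity with edgeR/DESeq is claimed, and DESeq-style
mean-dispersion regression is out of scope. Counts are linearly rescaled
to the geometric mean of the TMM-adjusted effective library sizes (in
place of quantile adjustment). The common dispersion maximizes the exact
conditional likelihood of replicate counts given their group sums — for
i.i.d. NB replicates this conditional distribution is free of the mean
parameter, so no per-sequence means need to be profiled out. Tagwise
dispersions are per-sequence moment estimates (pooled within groups)
shrunk toward the common value with configurable weight (default 0.7).
The per-sequence test conditions on the total of the two group sums; each
group sum is NB with shape n_g/α, and the one-sided p-value is the
inclusive upper conditional tail of the amplified sum, reported as 1
whenever that sum is at or below its conditional expectation (the test
measures enrichment only; this convention leaves the rejection region for
any α < 0.5 unchanged and keeps null calibration intact, verified by
simulation). In the α → 0 limit the conditional law is binomial, which
the tests use as an independent oracle. BH adjustment is delegated to
statsmodels.

## Overlap analysis

The draw probability of a peptide in one uniform NNK draw is the product
of per-residue degeneracy/32 (amber counts toward Q, so Q has two codons);
these probabilities sum exactly to 1 over the 20^L peptides of any length,
verified by brute-force codon enumeration for L ≤ 3. The random-library
null compares a literature list against m i.i.d. NNK draws (with
replacement — a library of m clones, not m unique peptides; intersections
use the resulting unique set): analytic expectation Σ[1 − (1 − pᵢ)^m],
checked by bootstrap. The subset null draws uniform subsets of an observed
library without replacement (hypergeometric expectation). Hit rates are
exact set intersections on deduplicated, uppercased inputs; list loading
drops annotated entries with non-standard letters.

## Figures

Stacked bars bin sequences into (N₁, N₂] abundance bins with edges
1, 0.3, 0.1, 0.03, … (exact decade values, extended downward as needed);
count-1 sequences always form the separate singleton segment. Segment
height is the bin's read fraction and width log10 of its unique-sequence
count; rendering widens zero-width (U = 1) segments to a 0.3 floor without
touching the stored layout. Scatter grids place sequences absent from one
library on an off-axis band at half that axis's minimum observable
abundance — a drawing convention; the class labels carry the meaning. All
figure-data builders are pure functions.

## Problem sizes and numerical choices

The test-suite and acceptance simulations use 2 × 10³–2 × 10⁴ clones,
10⁵–4 × 10⁵ reads and 5–13 replicates — scaled-down analogues of the real
runs (10⁶–10⁹ clones, ~4 × 10⁶ reads) chosen so the full suite executes in
about a minute while every rate being tested (filter pass rates, QQ
slopes, type-I errors, recovery fractions) has small enough Monte-Carlo
error for its stated tolerance. Ties in count ordering break
lexicographically everywhere, making every scan deterministic. Empty
inputs raise; an empty demultiplexing stream reports a NaN mapped
fraction. All randomness flows through explicitly seeded numpy
Generators; identical seeds give byte-identical FASTQ and count tables.

## Known limitations

- The NB pipeline trades edgeR's quantile adjustment and empirical-Bayes
  dispersion shrinkage for simpler, testable analogues; with few
  replicates and very low counts its power is modest, mirroring the known
  weakness of count models in that regime.
- Mutant removal discards reads rather than reassigning them, slightly
  deflating parent counts.
- The emulsion model is phenomenological (no droplet occupancy); it
  cannot reproduce loading-regime effects such as multiply-occupied
  droplets at high titer.
- Barcode matching is exact-prefix; platforms with indel-prone starts
  would need a tolerant matcher.
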