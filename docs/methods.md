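# Methods

## Data model and assumptions

A tumor sample is modeled as a mixture of three read sources per
genomic segment: non-tumor DNA (fraction G, the *DNA admixture*; purity
is 1 − G), tumor cells carrying the segment's aberrant allele-specific
state (a, b) with clonality c, and tumor cells with the wild-type
(1, 1) state. Per-allele read rates are

    rA = G + (1 − G)(c·a + 1 − c)
    rB = G + (1 − G)(c·b + 1 − c)

All estimators invert parts of this forward map. Standing assumptions:
segments are internally homogeneous (a segmentation concern, upstream
of this package); informative SNPs are unphased and independent;
reference-mapping bias is ignored, so allelic fractions are symmetric
around 0.5 in the normal; at most one aberrant tumor subpopulation per
segment (a two-population mixture per segment, on top of the normal
cells).

## Beta estimation

An informative SNP is a position present in both pileups whose normal
allelic fraction lies in `[min_af_het_snps, max_af_het_snps]`
(defaults 0.2/0.8, a symmetric heterozygosity window wide enough to
keep true heterozygotes at moderate coverage while rejecting homozygous
calls). Within a segment, tumor allelic fractions
concentrate at β/2 and 1 − β/2. Because pileups store fractions rather
than counts, alternative counts are reconstructed as
`k = round(af · cov)`. Beta maximizes the folded two-component
binomial-mixture log-likelihood

    L(β) = Σ_i log[ ½·B(k_i; n_i, β/2) + ½·B(k_i; n_i, 1 − β/2) ]

on a 0.001 grid followed by bounded golden-section refinement in the
winning cell, clamped to [0, 1]. SNPs are weighted implicitly through
their coverage n_i. A segment's beta (and the matched-normal `n_beta`,
the same estimator on the normal pileup) is reported only when
`nsnps ≥ min_required_snps` (10) and mean coverage ≥ `min_coverage`
(20), mirroring the downstream defaults. `n_beta` is expected to be 1;
values below 0.9 flag germline copy-number variants and exclude the
segment from sample-level estimation.

### Error table

Beta uncertainty is tabulated by Monte Carlo: for each (SNP count m,
coverage c) grid pair and each true β in a small grid, `reps` (default
1000) replicate segments are simulated at fixed coverage c and
re-estimated; the stored half-width is the 0.9-quantile of
|estimate − truth|, maximized over the β grid (a conservative,
β-independent bound). Off-grid lookups use the nearest grid value on
each axis. The builder evaluates the identical likelihood on the 0.001
grid only, without golden-section refinement: the refinement moves the
estimate by less than the grid step, which is itself below Monte-Carlo
noise at these replicate counts, and the grid-only form vectorizes
across replicates. Agreement between the two paths is tested. The
bundled table (grids 5–400 SNPs × coverage 10–500, seed in the file
header) ships as package data and can be regenerated with
`scripts/build_default_error_table.py`.

## Ploidy

Coverage normalization by each sample's mean makes wild-type segments
of an aneuploid genome sit away from logR 0; the displacement (shift)
gives `ploidy = 2·2^(−shift)`. The quantity this measures is the
average DNA content per cell of the *sample*: with admixture G and
tumor-cell ploidy ψ it equals `2G + (1 − G)·ψ`. The simulator's truth
record exposes this as `ploidy` (what the estimator should recover) and
the tumor-cell-only value as `tumor_ploidy`.

The shift search keeps balanced segments (beta ≥ 0.90 after the
coverage/SNP filters, `n_beta` ≥ 0.9), discards the lowest-logR 5% as
putative homozygous deletions, smooths the remaining logR values with a
Gaussian KDE (Silverman bandwidth) weighted by segment length, and
takes the leftmost local maximum whose basin mass is at least 20% of
the dominant mode's. Leftmost, because balanced states above diploid
(4, 6, ...) produce additional modes strictly to the right of the
wild-type mode; the 20% mass floor suppresses noise modes and is this
package's calibration. Genomes with no wild-type mass are genuinely
ambiguous (two (ploidy, admixture) interpretations can explain the same
profile); the estimator never switches interpretation on its own —
`--force-shift` and the check-plot lattice exist for exactly that
manual decision.

## DNA admixture

A clonal hemizygous deletion at admixture G shows β = 2G/(1 + G), so
each candidate deletion yields an apparent admixture G' = β/(2 − β);
subclonal deletions inflate G'. Candidates need β < 0.90, `n_beta` ≥
0.9, and ploidy-adjusted logRp in [−1.2, 0); they are retained when
|logRp − log2((1 + G')/2)| ≤ 0.25, i.e. their total-coverage signal is
consistent with a clonal one-copy loss (this also rejects CN-LOH, whose
logRp ≈ 0). The estimate is the leftmost KDE mode of the retained G'
values — the most clonal deletions — and the bounds re-evaluate G' at
β ∓ the error-table half-width over the supporting segments (those
within 0.1 of the mode), taking medians. The window slack (0.2) and
consistency tolerance (0.25) are this package's calibration, validated
by the simulation-recovery tests. When no candidate survives, the
estimator raises instead of returning a default: a copy-number-quiet
genome and a near-fully admixed sample are indistinguishable from these
data.

## Allele-specific copy number

With logRp = logR − shift,

    cnP = (β·2^logRp − G)/(1 − G)
    cnM = ((2 − β)·2^logRp − G)/(1 − G)

(the simplified major-allele form; it is algebraically identical to the
two-term form and remains defined at β = 0 — the equivalence is
asserted on a dense grid in the tests). Outputs are ordered cnA ≥ cnB
since the parental assignment is arbitrary.
`log2_corr = log2((2·2^logRp − 2G)/(2(1 − G)))` is the logR the segment
would show in a diploid 100% pure sample, so `cnA + cnB =
2·2^log2_corr`; it is reported even when beta is undefined (total copy
number needs no allelic signal) and is NaN when the implied tumor copy
number is ≤ 0 (clonal homozygous deletion). Integer calls round half
away from zero and are defined only when strictly within
`allelic_imbalance_th` (0.5) of the integer; minor-allele values in
(−0.2, 0) are treated as 0 for the call only — noise near the axis —
with the fractional value preserved.

## Clonality

Wild-type signals (β ≥ 0.9 and |logRp| ≤ 0.1) are not analysed. Other
segments are fitted against every integer state 0 ≤ b ≤ a ≤ 8 except
(1, 1), minimizing over c ∈ [0, 1] the squared distance
`(β_exp − β)² + 0.25·(logR_exp − logRp)²`; the logR weight 0.25 balances
the two axes' noise scales and was calibrated on the
simulation-recovery tests. For the hemizygous deletion the closed form
`c = (1 − G')/(1 − G)` is evaluated as an analytic candidate alongside
the numeric optimum. The inverse map is exactly degenerate along some
directions — a clonal (2, 1) gain equals a 50%-subclonal (3, 1), and
high-copy LOH states at low clonality shadow many points — so states
with residuals within 0.0075 of the best are tie-broken by parsimony:
smallest total copy number, then highest clonality. Segments whose best
residual exceeds 0.05 do not fit any single-state mixture and are
reported `not.analysed` (e.g. the poor-cluster profiles that should be
dropped from downstream analysis). Clonality bounds refit the winning
state at (β_min, G_max) and (β_max, G_min); the status discretization
at threshold 0.85 is: `clonal` if even the lower bound clears the
threshold, `subclonal` if even the upper bound does not, with
`uncertain.*` prefixes when the bounds straddle it.

For SNVs, `t_af_corr = vaf·(2G + (1 − G)·cnT)/((1 − G)·cnT)` is the VAF
expected in a pure sample with the same copy state, and clonality is
`vaf·(2G + (1 − G)·cnT)/((1 − G)·m)` capped at 1, with cnT = cnA + cnB
of the containing segment (fractional, so subclonal copy states
propagate) and multiplicity m the smallest integer in
1..max(1, cnA_int) keeping the raw clonality ≤ 1.05 — the most
parsimonious consistent multiplicity. Bounds come from the admixture
bounds; SNVs in the upper `error_rate` (0.05) tail of the sample's
adjusted-VAF distribution are flagged `excluded` as likely copy-state
or mapping artifacts.

## Simulator

The generator draws informative-SNP positions uniformly at ~0.33 per kb
(the density expected from common SNPs), normal allelic fractions as
Binomial(cov, 0.5)/cov, and tumor fractions as Binomial(cov_t, p)/cov_t
with p the read rate of the allele carrying the alternative base
(assigned to either parent with probability ½ per SNP). Per-SNP
coverage is Poisson (the simplest overdispersion-free choice consistent
with the binomial read model); the tumor mean scales with local DNA
content relative to the genome average, which is what creates the
wild-type logR shift in aneuploid genomes. Segment logR gets Gaussian
noise (sd 0.05). SNV counts are binomial around the VAF implied by the
clonality model. Everything is deterministic given a seed.

What the simulator does **not** emulate: reference-mapping bias, GC and
mappability waves (uneven coverage), linked errors between neighboring
SNPs, segmentation errors (breakpoints are taken as exact), and
germline CNVs. Passing recovery tests therefore demonstrate correctness
of the inversion under the package's own generative assumptions, not
robustness to those artifacts on real data.

## Problem sizes and test design

Recovery tests run 50 randomized genomes of 22–40 segments of 150 kb
(~50 informative SNPs each at coverage 100), with admixture
Uniform(0.1, 0.6) and at least five clonal hemizygous deletions per
genome — enough segments per state for the density-based mode searches
to be meaningful while keeping the full suite fast. Randomized genomes
keep wild-type segments the dominant balanced population because
profiles without a wild-type anchor are inherently ambiguous (see
Ploidy above), and avoid subclonal states that exactly alias integer
states, which no (β, logR) method can distinguish.

## Known limitations

* One aberrant subpopulation per segment; nested or sibling subclones
  sharing a segment are fitted to the closest single-state mixture or
  left `not.analysed`.
* Admixture relies on hemizygous deletions; samples whose only
  aberrations are gains or CN-LOH raise an estimation error by design.
* The ploidy/admixture pair is identifiable only relative to the
  wild-type anchor; whole-genome-duplicated profiles admit a second
  interpretation that must be chosen manually (`--force-shift`).
* Integer calls and clonality degrade at low coverage or SNP counts;
  the error table quantifies this and the bounds widen accordingly.
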