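# Methods

sweepkit detects and characterizes domestication-era selective sweeps in
diversity panels of largely self-pollinating crops, where a wild relative
panel is available as a diversity baseline. This note records the exact
statistics computed, the modeling assumptions behind them, and the numerical
choices that matter for reproducing results.

## Diversity-ratio selection scan

For every SNP the expected heterozygosity in a sample is `H = 2p(1-p)`, with
`p` the alternate-allele frequency among called genotypes. The scan slides a
window of a fixed number of *consecutive SNPs* (default 500) along each
chromosome — windows adapt to marker density rather than physical length, so
every window carries the same amount of information. The trailing remainder
of a chromosome that cannot fill a window is dropped rather than scored from
fewer markers.

Per window we report the wild mean `H_w`, the cultivated mean `H_c`
(cultivated populations are pooled before computing frequencies), and the
ratio `H_w / H_c` as the **ratio of the window means**, not the mean of
per-SNP ratios: per-SNP ratios are undefined whenever a SNP is monomorphic
in the cultivated pool, and their mean is dominated by low-`H_c` outliers.
A window whose cultivated mean is exactly zero has lost all diversity; it is
flagged with an infinite ratio and ranks above every finite window.

Signature regions are the windows in the top tail of the ratio distribution.
The cutoff for a top fraction `f` over `n` windows is the `k`-th largest
value with `k = max(1, ceil(f*n))`; ties at the cutoff are kept, and
adjacent qualifying windows are merged into single regions.

## Population differentiation

Pairwise F_ST uses Hudson's estimator as a **ratio of sums** over sites:

    N_i = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_i = p1(1-p2) + p2(1-p1)
    F_ST = sum(N_i) / sum(D_i)

with `n1`, `n2` the called allele counts. The ratio-of-sums form avoids the
instability of per-site ratios at low-diversity sites. Weir–Cockerham theta
is available as a secondary estimator (`estimator="wc"`); the two agree
closely on balanced designs. Note that Hudson's estimator assumes the two
samples are drawn independently: evaluating it on literally duplicated
samples yields exactly `-1/(n-1)`, not zero.

Under the Balding–Nichols model used by the generator (below), a pair of
populations that each diverged from the common ancestor with parameters
`F_a` and `F_b` has expected pairwise F_ST of `(F_a + F_b)/2`, which is what
the parameter-recovery checks exploit.

## Linkage disequilibrium

`r^2` between two SNPs is the squared Pearson correlation of dosage vectors
over pairwise-complete samples (the composite measure — no phasing needed).
Monomorphic sites give NaN; fewer than two complete pairs is an error, not a
silent NaN. LD decay is summarized by binning pairwise `r^2` by physical
distance (default 10 kb bins to a 1 Mb horizon) and reporting the left edge
of the first non-empty bin whose mean falls below a background level
(default 0.1). If the background is never reached within the horizon the
result is flagged instead of extrapolated.

## Significance thresholds

Two genome-wide thresholds are provided: plain Bonferroni `alpha/n` over the
SNP count, and an LD-adjusted threshold `alpha/(G/L)` that counts one
effective test per LD bin of length `L` in a genome of size `G`. For a
730 Mb genome with a 150 kb LD extent the adjusted threshold is 1.03e-5,
order of magnitude 1e-5; Bonferroni over 265,487 SNPs at alpha 0.05 is
1.88e-7. `nearest_power_of_ten` rounds a threshold to its order of
magnitude for reporting.

## Two-locus haplotype sharing

To ask whether two cultivated groups inherited the *same* swept haplotype,
we compare the sets of two-locus haplotypes they carry across consecutive
SNP pairs in the region. Haplotypes are read only from individuals that are
**homozygous and called at both sites of a pair**, which makes the statistic
phasing-free; in a predominantly selfing crop most individuals qualify, so
little information is lost. For each pair of populations:

    sharing ratio = (number of two-locus haplotype types present in both)
                    / (number of types present in either)

summed over all consecutive site pairs **before** division (pooling first
keeps sparse pairs from dominating). The statistic is type-based — presence
or absence of a haplotype, not its frequency — so adding individuals whose
haplotypes already occur in both populations leaves it unchanged.
Populations swept onto the same founder haplotype score visibly higher
(~0.5–0.7 in simulation) than pairs with independent sweeps (~0.3–0.5).
About 100 SNPs over the swept region give a stable contrast; small sparse
SNP sets are noisy because background haplotype types dilute the signal.

## Interval overlap statistics

To test whether selection-signature regions co-locate with trait (QTL)
intervals, each chromosome's genetic map is tiled into fixed-width genetic
bins (default 30 cM; the last bin of a chromosome is truncated). A bin is
*hit* by an interval set if any interval overlaps it by more than 0 cM.
With `n` bins total, `l` hit by signatures, `s` hit by trait intervals and
`m` hit by both, the reported p-value is the hypergeometric upper tail

    P(X >= m),  X ~ Hypergeometric(n, l, s)

computed as `scipy.stats.hypergeom.sf(m-1, n, l, s)` and verified against
exact integer enumeration.

**Limitation.** The null model treats each trait feature as a single
sampled bin. Features that are wide relative to the bin width mark several
adjacent bins each; the induced clumping over-disperses `m` and makes the
test anti-conservative (empirically, type-I error ~0.11 at nominal 0.05
when features are as wide as the bins). The calibration experiments in the
test suite therefore use features that fit inside one bin, which matches
the null; users testing bin-sized features should interpret marginal
p-values with caution.

Physical and genetic coordinates are interconverted by piecewise-linear
interpolation over mapped markers (`numpy.interp`); positions outside the
mapped range raise an error rather than extrapolate. `anchor_interval`
expands a genetic interval to the nearest mapped flanking markers, the
conservative choice when a trait interval must be expressed physically.

## Seed-color phenotyping

Seed coat color is measured as RGB per seed (five seeds per genotype).
Channel means are taken in RGB with half-up rounding to integers, and the
mean color is converted to CIE-L\*a\*b\* (D65 illuminant, 2° observer):
sRGB gamma expansion, the linear-RGB-to-XYZ matrix, then the Lab transform
with the (6/29)^3 linearity threshold. The conversion is implemented
directly and verified against an independent reference implementation to
0.05 per channel; white maps to (100, 0, 0) and all grays have
|a\*|, |b\*| < 0.5.

## Synthetic data generator

The generator's defaults emulate a sorghum-scale domestication panel: ten
73 Mb / 77 cM chromosomes, a wild population of 31 samples at divergence
F = 0.02, and five cultivated races of 94 samples each whose divergence
parameters (0.06–0.64) are chosen so that the Balding–Nichols identity
`pairwise F_ST = (F_a + F_b)/2` reproduces realistic wild–race
differentiation; selfing rate 0.95 throughout. Sites per chromosome default
to 2,000 — desk-scale, not the full marker density.

Mechanics:

- **Allele frequencies.** Ancestral frequencies are Beta(0.8, 0.8)
  truncated to [0.05, 0.95] (by resampling); each population's frequencies
  are drawn from the Balding–Nichols distribution
  Beta(p(1-F)/F, (1-p)(1-F)/F).
- **Linkage.** Haplotypes are copied in fixed-length blocks (default
  150 kb) from a small founder pool (default 8 per population), which
  creates LD exactly out to the block length. Setting `n_founders=None`
  draws sites i.i.d. (linkage equilibrium); the F_ST recovery experiments
  use this mode because founder sampling adds drift of order `1/(2K)` per
  population that biases pairwise F_ST upward.
- **Selfing.** With probability `selfing_rate` an individual's second
  haplotype is a copy of its first, applied after sweeps.
- **Sweeps.** A sweep replaces each haplotype copy's segment with a cached
  swept founder haplotype with probability `1 - diversity_retention`.
  Sweeps sharing a `haplotype_id` across populations model a single
  domestication event; distinct ids model convergent, independent events.
  Retention 0 fixes the region completely (infinite scan ratio).
- **Truth records.** Every run returns the planted frequencies, sweep
  regions and founder assignments so that tests can score recovery without
  re-deriving the ground truth.

`simulate_intervals` places trait intervals either uniformly on the genetic
map or overlapping planted sweeps, for calibration and power experiments;
`simulate_seed_colors` draws per-seed RGB values around palette colors with
Gaussian channel noise clipped to [0, 255].

## Determinism

Every stochastic routine takes an explicit seed. The pipeline derives
per-stage seeds from one top-level seed via SHA-256 (`seed:stage`, first
four bytes, mod 2^31), so toggling one stage does not perturb the others.
Pipeline outputs contain no timestamps, and the manifest records SHA-256
checksums of every output; a rerun with the same configuration and seed is
byte-identical.

## Non-goals

The generator is a test harness, not a demographic simulator: no coalescent
machinery, no mutation/recombination-rate calibration, no realistic site
frequency spectra. The statistics target inbred diploid panels; the
haplotype-sharing statistic in particular discards heterozygous individuals
and would be underpowered in outcrossing species.
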