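# Methods

## Data model and filtering

A locus is a haploid multiple sequence alignment over `{A,C,G,T,N,-}`,
one record per individual megagametophyte. Because the tissue is haploid,
phase is observed and every pairwise LD table is a direct haplotype
count. Columns are classified once per alignment:

- any `-` in a column makes it an *indel column*, excluded from every
  statistic (indels are treated as alignment artifacts of the amplicon
  design, not variants);
- columns with three or more alleles among called bases are
  *multiallelic* and excluded (they violate the infinite-sites framing
  used throughout and are rare in the target data);
- the remainder are *monomorphic* or *biallelic SNPs*; biallelic SNPs
  split exactly into singletons (minor count 1) and parsimony-informative
  sites (minor count ≥ 2).

IUPAC ambiguity codes other than `N` are demoted to `N` on input: base
quality filtering happens upstream of this package, and an uncertain base
is safest treated as missing.

Two missing-data policies are exposed because the target surveys used
different conventions in different analyses and did not document which
applied where. `complete_deletion` (default for diversity statistics)
analyzes only columns with no missing base; `pairwise_available` (default
for LD) uses every column with ≥ 2 called bases, with per-site sample
sizes. Reports record the policy used.

## Diversity statistics

Watterson's estimator is θ̂_W = S/(a₁L) per site, a₁ = Σ_{i=1}^{n−1} 1/i.
π sums, over analyzed sites, the probability that a random pair of called
sequences differs there (under complete deletion this equals the mean
pairwise Hamming distance; under pairwise availability each site uses its
own called count, which keeps the estimator unbiased under missingness).
Tajima's D uses the standard a₁…e₂ constants; D is reported as undefined
when S = 0 rather than coerced to 0. Significance uses the
beta-distribution approximation of D's null density, rescaled to the
attainable range [D_min, D_max] computed from n — the approximation used
by the standard desktop tools this package is meant to reproduce, hence
preferred over a coalescent-simulated null (which remains available
through the simulator). Note the exact null mean of D is slightly
negative at finite θ (about −0.07 at n = 50, θ_locus = 5, confirmed
against an independent coalescent simulator); tests that check "D
centered at zero" use a band of ±0.1 with enough replicates that Monte
Carlo noise is small against the band.

Haplotype diversity is Hd = n/(n−1)·(1 − Σ p_k²) over distinct sequence
strings at analyzed sites; sequences still containing `N` at analyzed
sites (possible only under pairwise availability) are excluded because
haplotype identity is undefined with missing characters.

## F_ST

Global F_ST per locus is Hudson-style 1 − H_w/H_b. Per analyzed site a
population contributes the unbiased within heterozygosity
(1 − Σ p̂²)·n/(n−1) and a population pair contributes 1 − Σ p̂_a q̂_a;
H_w averages over populations, H_b over unordered pairs. The unbiased
within term matters: the plug-in version inflates F_ST by roughly 1/n,
which at the survey's deme size of 8 would manufacture differentiation
of ~0.12 out of panmixia. The cost is a known signature on one degenerate
input — feeding two literal copies of the same sample returns exactly
−1/(n−1) instead of 0, because the copies are not independent samples.
Real near-panmictic data (island model, 4Nm = 100) come out at the
few-percent level, matching the regime the generator emulates.

## Linkage disequilibrium

For a pair of biallelic sites, individuals called at both enter a 2×2
haplotype table (pairwise deletion, minimum 4 complete haplotypes; a
margin monomorphic after joint-missing removal drops the pair with a
logged reason). r² = D²/(p_A q_A p_B q_B) and D′ = |D|/D_max with the
usual sign-dependent D_max. Significance is a two-sided Fisher exact
test computed by exact integer hypergeometric summation (tables with a
zero margin return p = 1 by convention); the implementation is written
to agree with brute-force enumeration to floating-point precision, and
is cross-checked against both an exact-rational enumerator and
scipy.stats.fisher_exact in the tests. Bonferroni correction defaults to
a single global denominator over all retained pairs in the dataset
(matching the one survey-wide "percent significant" figure); a per-locus
scope is available and reports record which was used.

LD pruning is greedy and deterministic: offending pairs (significant and
r² above threshold, default 0.2) are visited in (locus, position) order
and the member with higher missingness (ties: higher position) is
removed; pairs already broken by earlier removals are skipped. The
procedure is intentionally simple — the surveys say only that linked
SNPs "were removed" — and its determinism is what matters for
reproducible STRUCTURE-input preparation.

## LD decay

Two models are fitted by unweighted least squares over all pairs (no
distance binning, matching how such surveys plot and fit):

- Hill–Weir expected r²: E[r²](C, n) with C = ρ_bp·d, the sample-size-
  adjusted drift expectation. One n enters the expectation; pooled fits
  across loci of unequal n use the mean n, recorded in the fit metadata.
- D′(t) = (1 − r(d))^t, r(d) = min(0.5, 0.01·(cM/Mb)·d/10⁶). The map
  scale defaults to 1 cM = 1 Mb with {0.5, 10, 20} supported; t is the
  number of generations since complete disequilibrium.

Both optimizations are 1-D, bounded below by 0, and use a fixed
log-spaced multi-start grid followed by bounded scalar minimization — no
stochastic restarts, so fits are bit-reproducible, and the returned
residual is asserted (in tests) to beat every grid start. The
threshold-crossing distance is the smallest integer d with fitted
E[r²] < threshold, found by bisection (the curve is monotone); a curve
already below the threshold at d = 1 reports 0 (the convention used in
the survey tables for loci whose fit starts under the cutoff) and a curve
that never crosses reports a `never_reached` sentinel. Note E[r²] floors
at ≈ 1/n for large C, so small samples genuinely never cross 0.2.

## Recombination rate

ρ = 4Nₑr per locus is estimated by pairwise composite likelihood: the
log likelihoods of all biallelic SNP-pair haplotype configurations are
summed, each evaluated at ρ_pair = ρ_kb·d_kb, and the candidate grid
maximizer is reported (per-kb, per-site and per-locus scalings are all
emitted because survey tables are ambiguous about the unit). A flat
profile — maximum within 2 log-units of the far grid edge — is flagged,
mirroring the survey's observation that small-sample likelihood curves
lack distinct peaks.

The two-locus likelihood table is generated by Monte Carlo: standard
neutral two-locus coalescent genealogies at each grid ρ, with
configurations drawn from branch-length exposure at each locus and trees
importance-weighted by W_left·W_right (total exposure product). This is
the small-θ limit of conditioning on each locus carrying exactly one
mutation; at the nominal table θ of 0.001/site, literal mutation
dropping would almost never yield a segregating pair, so the limit is
both accurate and orders of magnitude cheaper. +1 pseudocount smoothing
over the full configuration universe keeps composite log likelihoods
finite; configurations are canonicalized under allele relabeling at
either site and site swap. The grid is densest near 0 (`log_grid`)
because that is where the likelihood changes fastest. Tables are
reproducible under a fixed seed, writable to and readable from a
documented text dialect, and interchangeable with externally produced
likelihood files in that dialect; a header n differing from the
dataset's n is a hard error (no interpolation across sample sizes).

Missing data: each pair uses only individuals called at both sites. When
a pair's complete-haplotype count differs from the table's n (or the
pooled sample exceeds the n = 100 table cap), the configuration is
projected to the table's n by hypergeometric-expectation scaling with
largest-remainder rounding — an explicit, documented approximation in
the spirit of using fixed precalculated tables on data with missingness.
The lookup tables assume constant population size; on strongly expanding
demographies the estimator inherits an upward distortion (star-like
genealogies carry little LD), which is a property of the method, not of
this implementation.

## Resampling experiment

Within a densely sampled population, k (default 8) of its individuals
are drawn without replacement B (default 100) times; within each draw,
sites are re-filtered (complete deletion inside the subsample) and D and
π recomputed. Replicates with S = 0 have undefined D and are counted,
never imputed. Joint mode (default in the pipeline) reuses the same
drawn individuals across loci; an independent per-locus mode exists.
π is approximately invariant under subsampling while D loses rare
variants, so subsample means shift upward under expansion — the
mechanism behind the sample-size caution the experiment quantifies. The
latitude-trend table reports each population's mean D across loci beside
its latitude, with resampled means where available.

## Synthetic data generator

The generator is a Hudson-style ancestral recombination graph: lineages
carry ancestral-material segments over [0,1), labelled with descendant
sets; events are within-deme coalescence, recombination at rate
(ρ/2)·span per lineage, and symmetric island migration at rate M/2 per
lineage; exponential growth multiplies the coalescence intensity by
e^{gt} backwards in time (event times solved in closed form). Mutations
are poured onto segment-time exposure at rate θ/2 per unit material and
assigned to the segment's descendant set, so no explicit tree storage is
needed. Time is in units of 2N generations with θ = 4Nμ and ρ = 4Nr per
deme.

Infinite sites on a finite grid: each mutation maps to column
⌊u·L⌋+1; collisions walk to the nearest free column, keeping mutations
local to their genealogical position. Derived alleles are drawn uniformly
from the three non-reference bases over a random reference sequence.

Defaults emulate the survey design: 11 loci with the survey's amplicon
lengths (1.5–7.2 kb, mean 3.7 kb) and per-locus sequenced fractions
(~29% on average, as two end windows masked to `N` elsewhere), 10
populations of (8,8,24,8,24,8,8,8,8,24) haploid samples (128 total),
θ = 0.005/site, ρ = 0.003/site (the survey's multilocus ρ/θ ≈ 1.8
regime), island migration 4Nm = 100 (near-panmixia, F_ST at the
few-percent level), and growth rate 5 per 2N generations — chosen once
so that simulated mean Tajima's D (≈ −1.0 at survey sample sizes) sits
in the expansion regime such surveys report (observed −0.88). A single
seed drives genealogy, mutation, masking and reference.

What the generator does *not* emulate: per-individual read-length
variation (masking is shared across individuals), sequencing error,
gene conversion, selection, and real recombination-rate heterogeneity
along loci. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean neutral model with survey-shaped
sampling — not robustness to artifacts real chromatograms would add.

## Problem sizes and numerical choices

Stochastic test suites use fixed seeds chosen up front and problem sizes
a desk machine handles comfortably: 300–1200 replicates for simulator
calibration (Watterson agreement to 5%, neutral D centering), 500
replicates for the growth shift, 20 replicates per ρ level over
{0, 5, 20, 50} for rank recovery (Spearman > 0.7) with a 14-point
log grid and 1200 Monte Carlo genealogies per grid cell at n = 50, and
50 growth loci for the subsampling shift. The acceptance script scales
the same experiments to run in a few minutes. Lookup-table cells that
produce no usable genealogy raise rather than silently flattening the
likelihood. Optimizers are deterministic; all randomness flows from
explicit integer seeds recorded in outputs.

## Known limitations

- The composite-likelihood ρ estimator is consistent in rank but not
  calibrated in absolute value under model misspecification (growth,
  projection across n); per-locus values should be compared, not
  interpreted as unbiased point estimates.
- The beta approximation for D's significance is approximate in both
  tails; a simulation-based p-value via the generator is the alternative
  when exactness matters.
- Fisher exact enumeration is exact but O(n) per table; for sample sizes
  far beyond this package's design range a normal approximation would be
  preferable.
- The D′(t) decay model inherits the assumed physical-to-genetic map
  scale; fitted t values scale inversely with it (exactly, in the
  small-r regime) and are only comparable at a fixed assumed scale.
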