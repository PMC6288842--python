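# Methods

This note records the models behind `whitemap`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate.

## Cross design and the simulator

The unit of analysis is one F1 outbred full-sib family: two wild-caught
parents and N offspring genotyped at biallelic SNPs. The simulator
(`synthetic_cross`) draws a ground-truth genetic map and meioses from it:

- **Meiosis model.** Crossovers are interference-free, so haplotype origin
  along a chromosome is a two-state Markov chain; the switch probability
  over a sex-specific distance *d* cM is the Haldane recombination fraction
  `r = (1 − e^(−2d/100))/2`. The downstream estimator uses the same mapping
  function (`d = −50·ln(1−2r)`), making simulator and estimator mutually
  consistent. Interference models (e.g. chi-square/Kosambi-consistent
  crossover processes) are out of scope.
- **Heterochiasmy** is a uniform expansion factor applied to male distances
  to obtain female distances. Real sex differences are regional rather than
  uniform; a single factor matches the genome-wide female:male map-length
  summaries the pipeline reports, which is what the tests check.
- **Segregation types** are drawn i.i.d. per marker from a configurable
  mixture of mother-informative (Aa × aa), father-informative (aa × Aa) and
  double-heterozygous (Aa × Aa) markers. The default mixture (0.4, 0.4,
  0.2) reflects that single-parent-informative markers dominate informative
  RAD SNP panels; the true proportions of any given cross depend on
  population heterozygosity and are configurable.
- **RAD multi-SNP loci**: each locus carries 1–4 SNPs (default proportions
  0.60/0.25/0.10/0.05) at identical positions, giving the SNP-thinning
  filter realistic input. The "4 or more" class is simulated as exactly 4
  because the thinning rule removes every locus with more than three SNPs
  regardless of the count.
- **Genotyping error** replaces a call with one of the two other genotypes
  uniformly (default rate 0.001); **missingness** masks calls i.i.d.
  (default 0.05, comfortably under the 20% per-locus filter). The symmetric
  error model is the simplest one that reproduces the well-known
  map-inflation effect of genotyping errors.
- **Scale defaults** mirror the study design: 156 offspring, 40 groups,
  135 SNPs per group, mean male inter-locus spacing 0.43 cM (total length
  divided by SNP count in the published sex-averaged map), female expansion
  1.09 (the published total-length ratio).

Determinism: every stochastic step derives its generator from
`SeedSequence([seed, stage])`, so one config seed fixes the VCF bytes.

## Informative-locus filters

Classification is a pure function of the parental genotypes; markers with a
missing parental call are uninformative and dropped. Double-heterozygous
markers are informative only through homozygous offspring (a heterozygous
offspring does not reveal which parent sent which allele).

- RAD loci with >3 SNPs are removed (likely collapsed paralogs); loci with
  2 *or 3* SNPs are thinned to one SNP chosen uniformly. The treatment of
  exactly-3-SNP loci is a judgment call (the filtering convention in the
  field states the >3 and the 2-SNP cases explicitly); thinning to one SNP
  is consistent with the one-SNP-per-locus intent.
- Missingness: strictly greater than 20% missing offspring calls removes
  the marker (31/156 = 19.9% is kept, 32/156 is removed).
- Segregation distortion: Pearson chi-square goodness of fit, no continuity
  correction, against 1:1 (single-parent-informative) or 1:2:1
  (double-het); p < 0.001 removes the marker. A variant that tests only the
  homozygote classes 1:1 is available (`both_inf_test="homozygous"`)
  because mapping software differs in whether the heterozygote class enters
  the test; the three-class version is the default. Markers with zero
  informative offspring are removed with a warning. The filter's realized
  type-I error on undistorted simulations is consistent with the nominal
  0.001 (acceptance suite, ≥50 000 markers).

Hard genotype calls are used throughout; converting to genotype likelihoods
(as likelihood-based mapping software does) is a documented simplification
— with the parental-library sequencing depths this pipeline assumes,
parental genotypes are effectively known, and offspring uncertainty mainly
costs information rather than biasing two-point counts.

## Two-point estimation

The substrate is the transmission matrix: per parent and marker, the allele
that parent transmitted to each offspring where the offspring call reveals
it. Phase is unknown, so recombinants between two markers are counted under
an arbitrary phase and folded, `r̂ = min(f, 1−f)`; the LOD against free
recombination is `k·log10(2r̂) + (n−k)·log10(2(1−r̂))` with the `n·log10 2`
limit at zero recombinants. All-pairs counting is vectorized as indicator
matrix products.

**Double-heterozygous pairs.** For Aa × Aa pairs in repulsion phase the
doubly homozygous offspring that counting relies on are nearly absent
(a handful of meioses), which is catastrophic for distance estimation. The
package therefore estimates all double-het pairs by EM over the two-locus
transmission likelihood: hidden variables are the four transmitted alleles;
both parental phase structures (same/opposite) are fit and the higher
likelihood kept; convergence at |Δr| < 1e-6 or 100 iterations. Because the
offspring genotype is the *sum* of the two transmitted alleles, the
likelihood is symmetric in the parents' recombination fractions — sex-
specific r is unidentifiable from such pairs — so the EM estimate enters
only the joint (grouping/ordering) matrices; the per-parent matrices keep
the counting estimates with their honest meiosis counts. The EM is
vectorized over all pairs via the nine two-locus genotype class counts.

Mother-informative × father-informative pairs share no informative meioses;
their two-point estimate is undefined and the pair is skipped. Such markers
join groups transitively through double-het markers.

## Grouping

Single-linkage transitive closure over pairs with joint LOD ≥ 16
(inclusive, since the threshold semantics of mapping software are not
standardized an inclusive link is the less surprising choice), minimum
group size 25; smaller components dissolve into an unassigned pool rather
than being force-merged. Raising the LOD limit can only split groups
(monotonicity), which the tests assert.

## Ordering

The criterion is SARF — the sum of adjacent recombination fractions — but
computed on a *denoised* working matrix. Rationale: at the study's density
(~2 cM between markers, ~150 meioses) the standard error of adjacent r̂
equals the signal, and the minimum-SARF path through the raw estimates
undercuts the true order by chaining through downward-fluctuated pairs
(measured: the true order's raw SARF is about twice the heuristic optimum,
and the resulting folded orders inflate map lengths by 30–100%). The
working matrix is built by:

1. completing pairs with no direct estimate by the shortest additive
   Haldane distance through markers informative with both (a tiny 1e-6 cM
   floor keeps perfectly linked pairs as graph edges);
2. fitting a 1-D coordinate per marker by weighted MDS (SMACOF, classical
   MDS start; weights are inverse variances of the distance, zeroed for
   r̂ ≥ 0.4), followed by one refinement pass using only pairs within 30 cM
   of the first-pass coordinate;
3. converting coordinate gaps back to recombination fractions.

On this matrix the optimum is the monotone order of the coordinate, and the
spec'd machinery — farthest-pair-endpoint greedy insertion, 2-opt segment
reversal, best of three seeded restarts (ties to the lowest run index),
orientation canonicalized by endpoint marker ids — reliably attains it; on
groups of ≤8 markers it matches exhaustive enumeration in 100% of runs
(acceptance suite). A disconnected estimate graph raises an error naming
the group.

## Map distances

Interval lengths along the order are fitted per sex by non-negative
weighted least squares (NNLS): every pair of markers informative in that
parent whose structural separation (embedding coordinate gap) is at most
20 cM — plus every consecutive informative pair, which always anchors its
own interval — contributes one equation `Σ δ_k = −50·ln(1−2r̂)`, weighted by
its meiosis count. Two deliberate choices:

- *Selection by structural distance, not by the pair's own estimate.*
  Including pairs conditional on their own noisy d̂ truncates the error
  distribution and biases lengths downward (measured at −10 to −25%);
  selection by the independent embedding coordinate removes that bias.
- *The 20 cM window* keeps pairs in the range where the folded counting
  estimate is precise and the convexity of the Haldane transform is
  negligible; it was calibrated on simulations with known truth, where it
  gives per-group sex-averaged lengths accurate to ~7% on average and an
  essentially unbiased total.

The female map uses the mother's meioses, the male map the father's; a
marker with no information for the requested sex sits at the running
position (contributing 0 cM), and a group with no informative markers for
one sex has length 0 in that sex's map. The sex-averaged position is the
mean of the female and male positions: interval-wise pooling across
interleaved single-parent chains double-counts spans (a four-marker worked
example inflates ~33%), whereas the mean matches the pooled-meiosis limit
where both sexes are informative and reproduces the published behaviour of
single-sex groups, whose sex-averaged length is half the informative sex's
length. Fitted intervals above 50 cM (including r̂ = 0.5) are capped there
with a warning; the cap is configurable.

## Map statistics

Group length is the last marker's position; cM-per-marker is length/SNPs
(in the published table this is what the density column contains, so the
fixture names it `cM_per_marker`); the global mean spacing is the
unweighted mean of per-group values, with the whole-map alternative
(total length / total SNPs) exposed under `overall_cM_per_marker_*`. The
female:male ratio is reported both from summed totals and as the mean of
per-group ratios over groups positive in both sex maps; with the published
table both raw-length and printed-rounded per-group ratios agree to two
decimals, and raw lengths are used. The packaged 40-group table is verified
against a stored sha256 at load.

## Synteny

Mapping records (marker, chromosome, bp, MAPQ) are read from TSV or SAM;
the alignment step itself is out of scope, so any aligner's output can be
supplied. Records at MAPQ ≤ 30 are removed (strict inequality; MAPQ > 30
means a mapping error rate below 1e-3), as are markers absent from the map.
Each group's homolog is the modal reference chromosome of its retained
hits; ties break to the lower chromosome number and are flagged
`ambiguous` — a silent choice would hide a genuinely undecided assignment.
Groups are renamed W01..Wk ordered by (homolog number, median position of
majority hits).

Chromosome arms are 0-based half-open bp intervals with a rediploidization
class. Arms of mixed class are excluded *before* any computation, so the
expected count `N · length_a / Σ lengths` sums exactly to the retained hits
N on included arms (the conservation invariant). The expected/observed
ratio is undefined (NA) for arms with zero observed hits and such arms are
excluded from the test, mirroring the treatment of zero-hit arms in
published practice. The AORe vs LORe contrast is a two-sided Wilcoxon
rank-sum test: exact by enumerating rank assignments whenever the input is
tie-free and the enumeration is affordable (covers both samples ≤ 10 and
any split with n₁+n₂ ≤ 12), otherwise the normal approximation with tie
correction and continuity correction. The statistic reported is the
Mann-Whitney U of the AORe ratio set, so complete LORe depletion yields
W = 0.

The packaged arm table is *synthetic*: it reproduces the real
classification structure (30 AORe and 14 LORe arms plus 6 excluded mixed
arms over 29 chromosomes, with the published LORe and mixed arm names) but
its bp lengths are invented. Users with the real arm coordinates can supply
them as a CSV.

## What the synthetic tests show — and what they do not

Passing tests demonstrate that the implementation recovers known truth
under its own generative model: Haldane meioses, i.i.d. segregation types,
symmetric errors, i.i.d. missingness, length-proportional mapping rates.
Real data violate all of these in places — crossover interference, clustered
missingness, allele-specific error, paralogous RAD loci beyond the >3-SNP
rule, regional heterochiasmy — so the acceptance numbers (grouping ARI 1.0,
~7% mean group-length error, female:male ratio recovered to ~0.1, type-I
rate ~0.001) bound behaviour under the model, not under any particular
dataset. Absolute cM comparisons to published per-group lengths are not
attempted: the published maps come from multipoint-likelihood ordering with
its own distance conventions, and only table-derived statistics are
recomputed exactly.

## Problem sizes used in tests

The test and acceptance runs use scaled designs chosen to exercise every
code path while keeping the suites quick on a single CPU: recovery runs use
5 groups × 60 markers × 156 offspring (ten seeds), the ordering oracle 200
groups of 4–8 markers, the distortion calibration 50 000 markers, and the
synteny property runs a few thousand simulated mappings. The full
study-scale default (40 × 135 markers) runs in a few minutes and is used
for the pipeline demo rather than for the suites.
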