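# Methods

This note documents the statistical models, the numerical choices, and the
assumptions behind `popkit`, in enough detail to judge what a passing test
suite does and does not demonstrate.

## Data model

Genotypes are diploid, biallelic, unphased, coded per marker as the count of
the alternate allele (0/1/2) with −1 for a missing call. Positions are
1-based (as in PLINK .map/.bim and VCF); BED exports convert to 0-based
half-open. Chromosome labels are strings so sex-chromosome markers can exist
before QC. When a map file carries no genetic positions, centimorgans are
derived as bp/10⁶ (1 cM ≈ 1 Mb), the standard fallback for livestock arrays.
PLINK binary decoding follows the SNP-major 2-bit table with A1 treated as
the alternate (minor) allele by default; a flag flips the orientation. All
downstream statistics here are symmetric under ref/alt swap, so the
orientation choice is cosmetic.

## Quality control

Five filters run in a fixed order — chromosome keep-list, indel, call rate,
Hardy–Weinberg, MAF — and each removed marker is attributed to the *first*
filter that fails it, so report categories are disjoint and always sum to the
input count. The order matters only for the attribution, not for the survivor
set. Thresholds (defaults): call rate ≥ 0.90, HWE exact p ≥ 10⁻⁶, MAF ≥ 0.05,
autosomes 1–26. The MAF filter uses PLINK's inclusive semantics (keep
MAF ≥ threshold). The HWE test is the standard biallelic exact test:
enumerate every heterozygote count compatible with the observed allele
counts and sum the probabilities of all tables no more probable than the
observed one; computation is done with log-gamma terms and normalized in a
numerically safe way, and the test suite checks it against an exact
rational-arithmetic enumeration. Note the test cannot reject below
p ≈ 10⁻⁶ until roughly 25+ individuals genotyped — an intrinsic
granularity of the exact null, not an implementation limit.

## Diversity indicators

Per locus with alternate-allele frequency *p* (missing calls excluded),
*q* = 1 − *p*, over *n* genotyped individuals:

* Ho = heterozygote count / n.
* He = 2n/(2n−1) · (1 − p² − q²) — the small-sample-corrected gene diversity.
* PIC = 1 − p² − q² − 2p²q² (Botstein's form; for biallelic loci the printed
  squared-cross-term and classical forms coincide).
* Ae = 1/(p² + q²), the reciprocal of expected homozygosity;
  `ae_mode="observed"` switches to 1/(1 − Ho) for the literal
  observed-homozygosity reading.
* MAF = min(p, q); P_N = share of loci with MAF above a cutoff
  (default 0.01; the acceptance run uses the QC cutoff 0.05 over the pre-QC
  marker set, which is the convention that makes P_N ≈ retained/total).

For every biallelic locus PIC ≤ 1 − p² − q² ≤ He, with equality of zeros at
monomorphic loci; this is a property test.

**Ne from LD.** The point formula Ne = (1/4c)(1/r² − 1) needs a pair-selection
scheme that it does not itself specify. We compute r² as the squared Pearson
correlation of dosage vectors for same-chromosome pairs (missing dosages
mean-imputed), bin pairs by cM distance (default 0.25–5 cM in 0.25 steps),
subtract the 1/(2n) finite-sample term from each bin's mean r² (floored at
10⁻⁶), evaluate the formula at the bin midpoint in Morgans, and report
per-bin Ne plus the mean. Two caveats, verified against coalescent
simulations in the test suite: (1) the formula inverts Sved's
E[r²] = 1/(1+4Nc), which differs from the true coalescent expectation at
small 4Nc, so short-distance bins overestimate Ne — at c ≥ 1 cM the estimate
is within a factor of two of a simulated truth of 50; (2) rare variants
dilute r², so the estimator is meant for MAF-filtered (post-QC) input.

## Kinship, PCA, families

G = ZZ′ / 2Σpᵢ(1−pᵢ) with Z the dosage matrix centered at 2pᵢ; missing calls
are imputed to 2pᵢ (zero contribution after centering) and monomorphic
markers dropped. Frequencies default to the sample's own; a `freqs` argument
accepts base-population frequencies, which matters when the sample is itself
mostly close kin (own-sample centering then deflates within-family G — with
12 families of 50 the deflation is ≈0.02 and harmless, with 2 families it is
not). IBS distance uses only markers called in both members of a pair:
IBS per locus is 2 − |gᵢ − gⱼ|, D = 1 − (0.5·IBS1 + IBS2)/N.

PCA is an eigendecomposition of G; scores are eigenvectors scaled by
√max(λ,0), explained fractions are over the positive spectrum, and each
eigenvector's largest-magnitude entry is made positive so signs are stable
across linear-algebra backends.

Families: build a graph on individuals with an edge wherever G ≥ 0.1 (the
conventional half-threshold between half-sib ≈ 0.25 and unrelated ≈ 0) and
take connected components, so every within-family pair is linked by a chain
of relationships at or above the criterion. A complete-linkage alternative
(all pairs within a family above threshold) is available. Families are
numbered along the neighbor-joining leaf order of the IBS distance matrix.
NJ itself is the classical Saitou–Nei agglomeration with a deterministic
lowest-index tie-break; on additive inputs it reproduces the generating tree
exactly (tested to 10⁻⁹), and it is cross-checked against an independent
library implementation.

## ROH detection

The caller implements the array-standard windowing scheme with six criteria
(defaults: 50-SNP window; per-SNP qualifying-window fraction > 0.05; ≥100
SNPs; ≥1,000 kb; ≤50 kb/SNP; gaps ≤ 100 kb; ≤1 het and ≤2 missing). The
het/missing caps are applied in *both* roles: to qualify a window and to
accept the final segment. Two consequences deserve attention:

* Candidate runs are trimmed at both ends to the outermost called homozygous
  marker before the per-segment caps apply. Window qualification spills one
  or two markers past a true tract boundary (a window containing exactly one
  flanking het still qualifies); without trimming, those flanking hets would
  count against the segment cap and reject essentially every true segment.
  Segment boundaries therefore carry ±1 marker of fuzz, which is inherent to
  sliding-window ROH calling.
* At ~40–50 kb marker spacing the 100-SNP minimum implies a ≥~4–5 Mb minimum
  detectable run, regardless of the 1 Mb length criterion. Planted
  autozygosity is therefore recovered conservatively: the acceptance run
  reports both the recovered F_ROH and the planted truth side by side, and
  the recovery tests quantify the bias (planted F of 0.01/0.05/0.10 is
  recovered within ±0.01/±0.01/±0.02 on clean data).

A brute-force oracle — plain loops restating every rule — is kept in the test
suite and must agree with the vectorized caller exactly on hundreds of random
fixtures. Summaries bin segments into [1,5), [5,10), [10,15), [15,20), ≥20 Mb
classes with percentages to two decimals; per-chromosome coverage is the
union of segments over individuals divided by chromosome length; L_auto
defaults to the sum of observed per-chromosome spans, overridable with a
length table. F_ROH per individual is exactly ΣL_ROH/L_auto.

## Sweep scans

* **ROH islands**: per-marker incidence = number of individuals whose ROH
  covers the marker; threshold = the (1 − top_fraction) quantile (default top
  1%); markers at or above it merge into islands when adjacent with no
  sub-threshold marker between.
* **π**: per site, π = 2·c_ref·c_alt / (c(c−1)) with c = 2 × called
  individuals — the fraction of differing pairs among sampled alleles; no
  phasing needed. Window value = Σ site π / window bp; windows tile from
  position 1 with a 10 kb step, the final partial window is truncated and
  length-normalized; a window with markers but no variation is genuinely 0,
  a window with no markers is NaN.
* **Tajima's D**: per window, S = segregating sites, π_sum the unnormalized
  pairwise-difference sum, D = (π_sum − S/a₁)/√(e₁S + e₂S(S−1)) with the 1989
  constants computed from the haplotype count; with missingness the per-site
  allele counts vary, so the window's modal count is used and such windows
  flagged. D is NaN when S = 0 or the variance term is non-positive.
* **Region selection**: windows at or below the chosen lower quantile of the
  statistic (default 0.01) are selected and merged when overlapping or
  book-ended within one step. Ties at the discrete lower tail are all taken
  (on chip data many windows hold exactly one minimal-MAF variant and tie at
  the exact minimum); a degenerate all-equal scan selects nothing. Low π and
  negative D are the classic sweep signatures, hence the lower tail; both
  tail and quantile are parameters.
* **Annotation**: genes from BED or GFF3 (`gene` features) hit a region on
  ≥1 bp overlap in half-open arithmetic; per-method gene sets, all pairwise
  and three-way intersections (Venn counts) are reported. Exclusive Venn
  cells sum to the union — a property test.

## Synthetic data generator

The generator emulates a single-breed chip study: 26 autosomes of 100 Mb,
markers every ~40 kb (the density of a ~65k-marker array on a ~2.6 Gb
autosome set) with ±80% uniform jitter; 50 individuals as paternal half-sib
families (12 sire lines of 2–6 offspring, each offspring from its own dam);
founder haplotypes drawn i.i.d. per marker from a configurable MAF spectrum;
offspring by Mendelian gamete sampling with Poisson crossovers at 1 cM/Mb.
Spectra: `("uniform", lo, hi)`; `"chip"` (piecewise-uniform over five
0.1-wide MAF bins with array-like weights, heaviest at the ends);
`"neutral"` (density ∝ 1/p, the stationary neutral spectrum, with the lower
cutoff far below 1/(2n) so the sampled-site spectrum keeps its singleton
class — the configuration under which mean Tajima's D is ≈ 0, which the test
suite verifies over >10,000 windows). `maf_block_markers` lets consecutive
markers share a spectrum draw, mimicking the spatial autocorrelation of
allele frequencies along real chromosomes; without it, QC removals pepper
the map uniformly and split long ROH at >100 kb gaps far more often than in
real chip data.

Autozygosity is planted either as explicit tracts or to a genome-wide target
F: tract lengths are drawn uniform on 1–26 Mb (trimmed so the planted total
matches the target exactly), placed without overlap within an individual,
and forced homozygous by allele duplication; `het_error_rate` re-introduces
isolated hets inside tracts and `missing_rate` sprinkles no-calls.
QC-challenge markers (sex-chromosome, sub-threshold MAF, HWE-violating,
high-missingness, indel) can be appended in array-realistic proportions with
a per-marker truth label.

What the generator does **not** model: background LD among founders (markers
are drawn independently, so LD exists only within families — LD-based Ne on
generator output is therefore very large, and the Ne estimator is instead
validated on coalescent simulations), mutation, genotyping ascertainment
beyond the MAF spectrum, sex chromosomes' dosage, and selection. Passing
tests on this generator demonstrate the *operations* are correct under known
truth; they do not certify population-genetic realism of any particular
dataset.

## Acceptance run

`scripts/acceptance.py --seed N --out results/acceptance.json` regenerates
the study-scale dataset (50 rams, 12 sire lines, 26 × 100 Mb, ~40 kb
spacing, chip spectrum with 50-marker blocks, planted F = 0.01, call rate
99.8%, residual het error 10⁻⁴) and recomputes every reported quantity from
scratch; it also replays the report arithmetic on published chip-accounting
and ROH length-class tables, whose printed counts serve as inputs. Problem
sizes were chosen so the whole run completes in well under a minute on one
CPU. Expected behaviors worth knowing when reading the JSON: recovered
F_ROH sits below the planted 0.01 for the detection-floor reasons above;
mean Tajima's D is strongly positive because a chip MAF spectrum lacks rare
variants (ascertainment bias), unlike the neutral preset; and the three-way
gene intersection over a random annotation is small or zero, since the three
scans emphasize different signals unless a shared sweep is planted.

## Known limitations

* Only biallelic SNPs; multi-allelic VCF rows are rejected, PLINK 2 formats
  unsupported.
* Per-sample QC (call-rate or heterozygosity outliers) is out of scope; QC
  filters markers only.
* The gap-split + 100-SNP-minimum interaction makes ROH detection sensitive
  to post-QC marker density; users scanning sparser arrays should lower
  `min_snps` deliberately rather than trust defaults.
* GO/KEGG enrichment of candidate genes requires external services and is
  not included; the package emits gene lists and Venn counts.
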