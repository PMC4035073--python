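# Methods

## Data model

Cultivars are treated as essentially inbred: diploid genotype calls are
stored as HOM_REF / HOM_ALT / HET / MISSING, and heterozygotes are rare
residual heterozygosity or assay artifacts rather than true outbreeding.
Coordinates are 1-based inclusive base pairs; BED input/output converts to
and from 0-based half-open at the file boundary, and the conversion is its
own inverse. Cultivars present in the genotypes but absent from the
population panel are carried with group OTHER and excluded from group
statistics.

Allele frequencies count two copies per homozygote and one of each allele
per heterozygote; missing calls leave the denominator. A marker with no
non-missing call in a subset has an *undefined* frequency (NaN), never
zero.

## Diversity statistics

For a biallelic frequency p: MAF = min(p, 1−p), He = 1 − p² − (1−p)², and
PIC = He − 2p²(1−p)². PIC ≤ He always, with equality only at He = 0.
Population means include markers monomorphic within the population
(contributing 0) and drop all-missing markers. The sample-size adjustment
reports each mean as the average over `reps` (default 10) subsets of
`n_sub` (default 14) cultivars drawn without replacement — subsets, not
bootstrap resamples, because the original screen picks cultivars. A
population of exactly `n_sub` therefore reproduces the unadjusted value,
and smaller populations raise rather than silently extrapolate.

## Panel design

Two informativeness screens:

* **core screen** (founder set, default 14 cultivars): no missing calls and
  the minor allele carried by ≥ 3 cultivars (a heterozygote carries both
  alleles; monomorphic markers fail).
* **collection screen**: known map position, heterozygous-or-missing calls
  in at most 5% of accessions, and minor allele frequency strictly above
  2% (a MAF of exactly 0.02 is excluded).

Δ² between two markers is the squared Pearson correlation of allele
indicators over cultivars with homozygous non-missing calls at both markers
(pairwise-complete; phase is unambiguous in inbred homozygotes, so
heterozygotes are dropped pairwise). If fewer than two usable cultivars
remain or either marker is monomorphic in the usable subset, Δ² is
undefined (NaN) and the pair is skipped, not scored 0.

The panel-size simulation draws, for each size, `reps` uniform random
marker subsets, sorts each by position, and averages adjacent-pair Δ²
within chromosomes over pairs strictly inside (0, 1) — "mean complete LD".
The open-interval restriction follows the statistic's definition; a switch
(`mean_mode="all"`) averages every defined pair instead. Chromosome
boundaries never contribute pairs. The curve's per-size mean and standard
error across replicates are reported; the plateau, where additional markers
stop increasing the mean, indicates a practical panel size. The choice of
the final size is left to the user (the curve is reported, not
thresholded).

## Ancestry scan

A marker discriminates the parental pools when the absolute difference of
one fixed allele's frequency between PD and PO-indica exceeds the threshold
(default 0.7, strict). This is computed label-free: the frequency
difference of a fixed allele equals the major-allele frequency difference
for strongly diverged markers. The tracked indica allele is the PO-indica
major allele; a tie at 0.5 is broken alphabetically with a warning.

Adjusted HY = HY − PD − (1 − PO-indica) is left unclamped (range [−2, 1]);
0 means the HY pool matches the japonica parents, 1 complete indica
introgression with fully diverged parents. The statistic is not
antisymmetric under exchanging the pools: swapping pool roles and tracking
the japonica allele yields (2·PO − 2·PD − 1) − adjusted HY, a reflection —
with fully diverged parents, 1 − adjusted HY — so skew classes exchange
under relabeling, which is the meaningful invariance.

Windows tile consecutive runs of 5 discriminating SNPs per chromosome
(non-overlapping, so window values stay independent; a sliding variant
would only smooth the same signal). A terminal remainder window is
summarized and flagged `partial`. Quantiles use linear interpolation. The
genome-wide band is the 25th–75th percentile of *window medians*
(`band_source="markers"` computes it over per-SNP values instead); a window
median strictly above/below the band is INDICA_SKEWED/JAPONICA_SKEWED. By
construction of a quartile band roughly half of all windows fall outside
it; the biologically interesting regions are the *runs* of same-class
windows, which are merged into intervals bounded by their first and last
member SNP. A degenerate band (all windows equal) yields all-NEUTRAL.

Genome types: the indica-allele fraction at discriminating SNPs (homozygote
1, heterozygote 0.5, missing excluded) classifies a cultivar JA (≤ 0.3),
IN (≥ 0.7) or MX. These two thresholds are configuration defaults chosen
to separate visually dominant classes, not estimated quantities; they are
echoed in the output attributes, and cultivars missing at more than half
the discriminating SNPs are flagged low-confidence.

## Association mapping

The scan fits y = μ + xβ + u + e with u ~ (0, σ²g·K), e ~ (0, σ²e·I).
K is the VanRaden genomic relationship matrix (centered dosage
cross-product over polymorphic markers scaled by Σ2p(1−p); missing dosages
mean-imputed for this computation only). The variance ratio
λ = σ²g/σ²e is estimated once per trait on the null model by profile REML —
a bounded scalar search over log₁₀λ ∈ [−10, 10] with tolerance 1e-6 on the
eigendecomposition of K — and then held fixed for every marker test
(P3D/EMMAX). Each marker is tested by GLS on whitened data with an
F(1, n−q−1) statistic; with K = I the whitening is a scalar and the scan
reduces exactly to OLS. Markers monomorphic among the phenotyped lines, or
failing the association filter (MAF ≥ 0.05 and call rate ≥ 95% by
default), are skipped and logged; missing dosages at tested markers are
mean-imputed. Degenerate inputs are handled explicitly: a constant
phenotype reports β = 0 and P = 1 everywhere.

Permutation P-values are family-wise: the phenotype vector is permuted
across cultivars (seeded), the genome-wide maximum F is recorded per
permutation, and perm_p = (1 + #{max F ≥ F_obs}) / (n_perm + 1). The
add-one estimator bounds perm_p below by 1/(n_perm+1); the smallest
reportable value at 999 permutations is 0.001. λ is not re-estimated per
permutation (P3D), so each permutation costs one whitened OLS pass and the
whole null distribution is computed with matrix products. Fewer than 100
permutations triggers a resolution warning.

The pipeline's default association marker set is the discriminating SNPs
whose window is skewed — the study logic of testing SNPs that represent
frequently introgressed regions — with `"all"` and explicit lists
available. Significant markers (perm_p strictly below α = 0.01) in
non-neutral windows are annotated against a user-supplied feature catalog:
a closed window of ± 2 Mb around the SNP, GENE features in the matching
trait category first, QTL features only if no gene overlaps, an unknown
category dropping the filter with a warning. Allele-effect tables report
trait mean ± sample SD (ddof 1, undefined below two cultivars) per
homozygous allele class; heterozygotes are excluded from the table but
enter the regression with dosage 1.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
rice breeding history:

* **Parents.** Two homozygous pools; a configured fraction of markers
  (default 0.7) carries a fixed allele-frequency difference (the alt allele
  is always the indica-enriched allele), the rest draw a partial divergence
  from Beta(2, 2) on top of a uniform base frequency. Markers are allocated
  to chromosomes as evenly as possible with uniform positions, so no
  chromosome falls below an analysis window. Parent genotypes are clean
  (het/missing noise is applied to progeny only).
* **Progeny.** Each HY line is a Markovian ancestry mosaic: exponential
  segment lengths (default mean 5 Mb) with i.i.d. segment origins at the
  background indica probability (default 0.3) — a first-order approximation
  of a pedigree mosaic; no explicit generations are tracked. Selection at a
  skew region is modeled by resampling the whole-region origin per cultivar
  toward the target frequency (default 0.9), since the analysis consumes
  only the resulting frequency skew. The genotype at a marker copies a
  random parent of the origin pool, which adds realistic within-pool
  sampling noise at partially diverged markers; heterozygous (0.5%) and
  missing (1%) calls are sprinkled last.
* **Phenotypes.** Unit-variance traits built from QTL dosages plus a
  kinship-distributed polygenic term plus Gaussian noise. QTLs are
  parametrized by target variance fraction (default 0.30 per QTL at trait
  heritability 0.5); each component is rescaled to its target sample
  variance and the non-QTL components are made in-sample orthogonal to the
  QTL dosages, so the realized variance decomposition matches the
  configuration. QTLs are planted at the nearest fixed-difference marker
  that segregates in the progeny (MAF ≥ 0.05): a non-segregating locus
  carries no mappable signal. Heritability 0 yields pure noise.
* **Features.** One GENE feature at each planted QTL (its trait as
  category), plus decoy genes and QTLs elsewhere; decoys on QTL
  chromosomes get a foreign category so category filtering, not luck,
  excludes them.

Everything is reproducible from the config seed, and the truth set (skew
intervals, QTL records, per-cultivar origin tracks) suffices to score every
stage without re-reading the config.

**What passing tests on this generator do and do not show.** The generator
matches the analysis assumptions exactly: biallelic markers, homozygous
parents, Markovian mosaics, frequency-targeted selection and additive
QTLs. Real data add population structure within pools, LD in the parental
pools themselves, genotyping error beyond symmetric noise, non-additive
trait architecture and unbalanced group sizes; recovery rates measured
here are therefore upper bounds, and the permutation calibration — which is
distribution-free — is the result expected to transfer most directly.

## Problem sizes and numerical choices

Verification runs use desk-scale data chosen to keep the full suite fast
while leaving the statistics well-conditioned: 60 HY lines with 14 + 14
parents at 1200 markers on 12 x 30 Mb chromosomes for the end-to-end
recovery study (20 seeded replicates, 500 permutations per trait), 200
null traits at 500 permutations for the type-I calibration, and a
2400-marker, 3 Mb-block fixture for the LD curve — with 3 Mb ancestry
blocks the curve's rising phase is resolved at small panels and the
plateau premise (decay length much longer than spacing) holds from ~800
markers, while far longer blocks would make dense panels produce many
exact Δ² = 1 pairs that the open-interval mean excludes. Tolerances:
closed-form statistics are checked against brute-force oracles at 1e-12;
the K = I degeneracy against OLS at 1e-6 relative; affine-invariance of
nominal P at 1e-5 relative (limited by the REML search tolerance on λ).
Eigenvalues of K are clipped at 0; the Cholesky used for polygenic draws
adds a 1e-6 jitter.

## Known limitations

* No haplotype phasing and no HMM/probabilistic local-ancestry model; the
  scan is the frequency-threshold method by design.
* The MLM supports a user covariate matrix but no automatic
  structure (Q) correction, and tests one marker at a time.
* Association power at low-MAF markers in skewed regions is intrinsically
  limited (few minor-allele carriers), and the permutation null at such
  markers is heavy-tailed; the family-wise threshold absorbs this but
  single-marker nominal P-values there should be read with care.
* The quartile-band skew caller flags ~half the genome by construction;
  interpretation should rest on merged multi-window intervals, not single
  windows.
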