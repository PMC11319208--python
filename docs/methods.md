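# Methods

This note documents the models and procedures implemented in `hictopo`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic cohorts do and do not emulate.

## Contact matrices and balancing

All data live on a shared bin frame (`GenomeBins`): fixed-width, 0-based
half-open bins tiling each chromosome (default 10 kb). Only
intra-chromosomal matrices are stored; interchromosomal contact is
summarized as a single scalar mean, because its only downstream use is
the low-abundance cutoff. Matrices are symmetric and non-negative, with
a per-chromosome mask of excluded bins; every operation preserves these
invariants.

**Iterative correction (ICE).** Per chromosome, bin biases are iterated
(via matrix–vector products on an accumulated bias vector) until the
coefficient of variation of the non-masked marginals falls below `tol`
(default 1e-4, `max_iter` 200). The total non-masked sum is preserved,
so balanced entries remain on the raw count scale. Masked before
balancing are: zero-marginal bins, the lowest 2% of positive marginals
(a HiC-Pro-like percentile filter), and — beyond the percentile rule —
bins whose marginal is below 10% of the chromosome's median positive
marginal. The relative floor is load-bearing: ICE by construction
removes any factorizable coverage pattern, so a severely
contact-depleted locus (the ecDNA situation, below) would otherwise be
re-inflated to apparent typicality. Bins that cannot be balanced
meaningfully must stay masked rather than be normalized.

**Noise filter.** Contacts below ten times the average interchromosomal
contact frequency are treated as nonspecific ligation and set to zero
(boundary inclusive: a value equal to the cutoff survives). The filter
is applied only before enhancer–TSS contact quantification, never before
TAD or compartment calling.

## TAD calling

The caller is TopDom-style. For each bin the diamond signal is the mean
contact between the `w` bins upstream and `w` bins downstream
(truncated at ends; masked bins excluded from the mean). Candidate
boundaries are window-wide local minima over ±`w` bins, restricted to
bins with a complete diamond on both sides; candidates closer than `w`
bins (necessarily ties) collapse to the left-rounded positional midpoint
of their minimum-signal members. Each candidate is kept when a one-sided
Mann–Whitney test shows its diamond depleted relative to the pooled
diamonds centered one window away on either side — reference diamonds
have the same pair-separation profile as the candidate's, so the
comparison is not biased by distance decay (comparing against
within-domain *triangles*, whose separations are half as large, makes
every bin "significant" under any decaying contact model). Domains are
the intervals between retained boundaries; runs of masked bins split
domains, but only retained boundaries count as TAD *edges* — segment
ends created by coverage masking are artifacts, not architecture, and
chromosome ends are likewise excluded.

**Window optimization.** For each candidate `w`, TADs are called and
each TAD with ≥2 usable bins is scored by the mean pairwise Pearson
correlation of its bins' chromosome-wide contact profiles; the score of
`w` is the median over TADs and the argmax wins (ties to the smallest
`w`). On planted data the score — and the calls themselves — are nearly
flat for all `w` below the true domain scale and fall off sharply above
twice that scale, so the selection's practical role is to avoid the
harmful large-`w` regime; the tie rule then prefers small windows. The
selected `w` is exposed in the result rather than hard-coded.

## A/B compartments

Per chromosome: observed/expected (expected = mean contact per bin
separation over non-masked pairs), Pearson correlation matrix of the
O/E profiles over usable bins, then the leading eigenvector of the
column-centered correlation matrix. The sign is oriented so that
positive (A) bins have the higher mean gene density, the standard
convention; supplying a different orientation track flips labels
accordingly, and all outputs are invariant to global matrix scaling.

NA semantics are explicit rather than inherited from any particular
PCA implementation's failure modes. A bin is NA when (a) it is masked by
balancing, (b) its raw coverage is below 10% of the chromosome's median
bin coverage, or (c) its O/E profile has zero variance; a whole
chromosome is NA when fewer than 10 usable bins remain or the
correlation matrix is constant. Rule (b) is what reproduces absent
compartment calls over contact-depleted (ecDNA) loci. A locus-level
label is NA when more than half its bins are NA, else the majority call.

The cohort A:B track is `log2((#A + 0.5) / (#B + 0.5))` per bin, NA
calls excluded from both counts; the 0.5 pseudocount keeps small cohorts
finite.

## RCFS and ecDNA nomination

The regional contact frequency sliding-window score of bin *i* is the
mean contact over all bin pairs in the square window of `W` bins
centered on *i* (default `W` = 50 bins = 500 kb — local enough to be
sub-TAD, wide enough to integrate over noise), excluding the diagonal
and truncating at chromosome ends. Masked bins contribute zero to the
numerator while the denominator stays geometric (all off-diagonal pairs
in the window). This choice matters: averaging only over surviving pairs
would bias windows at the edge of a depleted locus *upward* (the
survivors are the near-diagonal flank pairs), inverting the signal the
score exists to detect.

A sample is **depleted** at a locus when its mean RCFS over the locus is
strictly below the cohort cutoff; ties are typical. The default cutoff
is the midpoint between the two centers of an exact two-class 1-D
k-means over the per-sample locus means (computed by the closed-form
sorted-split scan); a fixed numeric cutoff can be supplied instead.

**Corner signal.** Circularization brings the two ends of an amplicon
together; the corner signal is the mean contact between the first and
last `flank` bins (default 5) of the amplicon divided by the mean
distance-decay expectation at the same separations. It is quantified on
the raw count matrix with the raw-matrix decay: after balancing, the
amplicon bins' large bias divisors make the ratio incommensurable with
the underlying enrichment fold.

## SV topology

SVs are deletions, duplications and inversions (two breakpoints on one
chromosome). The support filter keeps records with size ≤ 50 Mb, ≥ 10
tumor paired-end reads, ≥ 10 tumor spanning reads and zero germline
reads (all boundaries as stated). The size-matched background draws, for
each SV, ten segments of identical size and type with start positions
uniform over all genome positions where the segment fits, rejecting
placements that touch an assembly gap; generation is deterministic given
a seed.

**Breakpoint signatures.** For each SV the submatrix with rows centered
on bin(bp1)±F and columns on bin(bp2)±F is extracted (F = 600 kb /
(2×bin width) = 30 bins, a 61×61 grid) and averaged elementwise within
SV type, with an occupancy count handling breakpoints near chromosome
ends; the identical procedure on background records gives the
comparison signature.

**Same-TAD enrichment.** Because an SV distorts its own sample's Hi-C
map, each sample's SVs are scored against the TAD sets of all *other*
samples: the per-sample fraction of SVs with both breakpoints inside one
domain, averaged over the other samples' TadSets, for real and
background records; a paired two-sided Wilcoxon signed-rank test across
samples compares the two, per SV type. The test is symmetric under
label swap and calibrated under the null by construction — provided the
real SVs are placed by the same mechanism as the background. (During
development, placing "uniform" SVs at bin starts without gap avoidance
inflated the null rejection rate to ~13%; the generator now places
non-planted SVs exactly like the background, and the null rate sits in
the nominal band.)

**Differential maps.** Per cell over a region,
`log2((mean_case + eps) / (mean_control + eps))`, median-centered over
the region; `eps` defaults to the 5th percentile of positive
control-group means, stabilizing empty cells without drowning signal.

## Multi-omic integration

The compartment battery compares, within each sample, a feature summary
over A-labeled bins against the same summary over B-labeled bins (NA
excluded from both), then tests across samples with a paired two-sided
Wilcoxon signed-rank and corrects the battery by Benjamini–Hochberg.
Three modes: base-fraction overlap (methylation domains, peaks, gene
bodies), point events per Mb of compartment (mutations; SV breakpoints
counted two per SV — interval overlap would double-count large SVs), and
mean TPM of genes whose TSS bin carries the label. The per-Mb modes are
the normalization that accounts for A compartments covering more of the
genome than B.

Consensus peaks are maximal regions where ≥ 2 samples have an
overlapping peak (sweep-line over per-sample unions). A candidate
enhancer is a peak whose overlapping-hypomethylation frequency across
samples is ≥ 10% (boundary inclusive). Enhancer–gene association uses a
Welch two-sample t-statistic of the gene's TPM between samples
hypomethylated vs not at the enhancer (Welch because group variances
have no reason to match; sign: positive = hypomethylated higher).
Enhancer contact sums are computed on filtered matrices: per bin, the
sum of contacts with all enhancer bins on the same chromosome, averaged
across samples for cohort tracks.

Copy-number classes per gene: on sex chromosomes amplified if min exonic
CN > ploidy×0.9, deleted if min CN < 0.75; on autosomes amplified if min
CN > ploidy×1.95, deleted if min CN < 1.1; biallelic loss (max CN < 0.5)
takes precedence over deleted. The precedence order only matters at
degenerate ploidy; at realistic ploidy the classes are mutually
exclusive.

## TAD-architecture subtyping

Samples are featurized by TAD edges per Mb in 1-Mb windows tiling the
genome, concatenated over chromosomes. Subtypes come from two-class
k-medoids (PAM; deterministic farthest-pair initialization plus seeded
restarts) on pairwise distances in feature space; the cluster with the
larger mean edge density is "narrow". The default distance is
**Euclidean**, not correlation: the subtype signal lives in both the
level and the positions of the edge density, and boundary-calling noise
makes the sparse (broad) group's rows mutually uncorrelated, so a
scale-free metric turns the broad group into a diffuse cluster (observed
mean within-broad correlation distance 0.75 vs 0.09 within-narrow, and
partition recovery collapsing accordingly). Correlation distance remains
available as an option. A t-SNE embedding is produced for visualization
only and never feeds the clustering, so results do not inherit its seed
sensitivity; a silhouette diagnostic over k ∈ {2,3,4} is emitted without
changing the two-class call. Subtype–omics associations use two-sided
Mann–Whitney tests with BH correction; covariates missing for more than
half the cohort are dropped with a warning.

## The synthetic cohort generator

Expected contact is
`depth · (1+d)^(−alpha) · f_tad^[same TAD] · f_comp^[same compartment]`
with Poisson observation noise; defaults `alpha` = 1 (the canonical
fractal-globule-range decay at these scales), `f_tad` = 3, `f_comp` = 2,
`depth` = 40 expected counts at one-bin separation. The toy genome is
two 20-Mb chromosomes at 10 kb (2,000 bins each); tests and the
acceptance battery use 6–10-Mb chromosomes so the full suite runs in
minutes while every planted structure stays at its intended genomic
scale. Broad TADs average 1 Mb; compartment state switches only at broad
TAD boundaries (as in real genomes) with a probability giving ~1.5-Mb
segments. Two fixed assembly-gap intervals per chromosome carry no reads
and no compartment label, and exercise the background rejection
sampling.

The **narrow subtype** is a recurrent architecture: one cohort-level set
of extra boundaries subdividing broad domains (~250-kb pieces, each
broad domain subdivided with probability 0.7) shared by all narrow
samples, so that subtype structure is a pattern discoverable across
samples; per-sample variation comes from counting noise and calling
error. Per-sample independent subdivisions would make the narrow group
internally uncorrelated, which contradicts the premise of recurrent
subtypes.

**SV plants** multiply contacts in a Gaussian-tapered neighborhood of
(bp1, bp2) by `f_sv` (default 8, exactly `f_sv` at the center cell).
Each sample draws 10 SVs (log-uniform sizes 50 kb–1 Mb) — denser per Mb
than patient genomes so cohort statistics have events at desk scale — of
which a configurable fraction (default 0.3) fails the support filter.
Placement is uniform and gap-avoiding like the background, optionally
biased toward A compartments (rate ×1.5) and/or forced intra-TAD with a
given probability.

**The ecDNA plant** models the *observed, post-sequencing* geometry: all
local contacts of the amplicon (internal and with the flanking
chromosome) are scaled by the depletion factor (default 0.05), because
the locus DNA resides mostly on circles and its chromosomal-context
contact collapses; a separate amplification fold exists for raw-count
experiments but defaults to 1, since balancing removes pure coverage
amplification (and per-chromosome sum-preserving ICE would otherwise
re-inflate any factorizable plant into the opposite of the published
geometry). The corner is planted as an absolute level — corner fold
(default 10) times the pre-plant decay expectation at the end-to-end
separation; a fold of 1 plants nothing. Under these defaults the
amplicon marginals fall below the balancing mask floor, RCFS collapses
over the locus, and compartment calls there return NA — the full
phenotype the detection chain is designed to recognize.

**Omics.** Gene TSSs are placed 2× denser in A (this is also what
orients the eigenvector); TPM is log-normal with an A-multiplier
(default 3) and a narrow-subtype multiplier (1.3). Mutations are
per-bin Poisson with a B-multiplier (2). HMR/PMD/5hmC intervals are
Poisson-placed with compartment biases (HMR and 5hmC denser in A, PMD
in B) and narrow-subtype multipliers (1.5); per-gene copy number is
Gaussian around ploidy 2 with an optional gain at a MYC-proxy gene in
narrow samples. Setting every multiplier to 1 yields a null cohort used
for the calibration checks.

**What the generator does not emulate:** real restriction-fragment
geometry, mappability and GC bias (ICE is exercised on synthetic
Poisson bias only), trans contacts (summarized as a scalar),
overdispersion beyond Poisson (a negative-binomial option is a known
gap), loops at anchor resolution, nested TAD hierarchy beyond one level,
realistic SV allele structure, and hg38 coordinates or real gene
annotations. Passing tests therefore demonstrate the statistical
machinery recovers planted structure under the stated noise model — not
performance on patient data.

## Benchmark problem sizes

The acceptance battery (scripts/acceptance.py, tests/test_acceptance.py)
runs: 50 random 200-bin matrices for ICE vs an independent alternating
fixed-point oracle; 20 seeds of ~20-TAD 10-Mb chromosomes for boundary
recovery; a 40-sample single-chromosome cohort (20 ecDNA+) for
RCFS/corner; 1,000 background placements; 200 null replicates (12
samples each) and 50 power seeds (30 samples, 70% intra-TAD) for the
SV–TAD test; a 4-sample cohort for signatures; a 20-sample cohort
through called compartments plus 40 truth-track null batteries for the
integration battery (this cohort carries 60 SVs per sample of ≤300 kb —
patient genomes harbor hundreds of SVs, and an order of magnitude fewer
events leaves a ×1.5 rate ratio unidentifiable by any paired test at
n = 20, while Mb-scale sizes on an 8-Mb toy chromosome create a
breakpoint edge effect near chromosome ends that is negligible at real
genome scale but would leak into the null); and 20 seeds of 15+15 broad/narrow cohorts
(2×6-Mb genomes) for subtyping. The full battery completes in roughly
five minutes on one CPU.

## Known limitations

- The boundary test's alpha (default 0.05) is not multiplicity-adjusted
  across candidates; the planted-truth precision target absorbs the
  resulting false-positive rate, and SV junctions in particular can
  masquerade as boundaries.
- The data-driven RCFS cutoff assumes the cohort actually contains both
  depleted and typical samples; on a homogeneous cohort the two-means
  split is arbitrary. Supply a fixed cutoff in that situation.
- `optimize_window`'s score is flat below the true domain scale (see
  above); it guards against too-large windows rather than identifying a
  unique optimum.
- Per-chromosome ICE without trans contacts cannot distinguish coverage
  amplification from genuine contact enrichment; the corner signal is
  therefore a raw-count quantity, and CN-aware normalization is out of
  scope.
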