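# Methods

This note documents the models implemented in `nmibcgen`, the
assumptions behind them, the synthetic-cohort generator used to
validate them, and the numerical and design choices made where the
analyses admitted more than one reasonable construction.

## Data model and conventions

All coordinates are 1-based, fully closed intervals, for both
mutations and allele-specific copy-number segments (the ASCAT
convention).  Normal copy number is fixed at 2; sex chromosomes are
not modelled by the toy genome, and real input restricted to autosomes
behaves identically.  Tables are tab-separated UTF-8 with a header
row; writers emit exactly the dialect the readers accept, so
write-then-read round-trips are identity — a property the test suite
checks.

## Mutation timing

The cancer cell fraction of a mutation with VAF *f*, purity ρ and
local total copy number CN<sub>t</sub> follows the standard linear
model: mutation copy number c = f·(ρ·CN<sub>t</sub> + 2(1−ρ))/ρ,
multiplicity m = round(c) clipped to [1, major], CCF = c/m.  The 95%
CI is a Clopper–Pearson binomial interval on the VAF propagated
through the (linear) CCF map; clonality is decided on the uncapped
interval (CI upper bound ≥ 1 ⇒ clonal), while the reported CCF is
capped at 1.

Two decisions deserve comment:

* **Early/late uses the integer multiplicity.**  On gained segments a
  clonal mutation is "early" when its mutation copy number exceeds 1.
  A late clonal mutation has *expected* continuous copy number exactly
  1, so thresholding the continuous value at 1 degenerates to a coin
  flip on read noise for that entire class; rounding first places the
  decision boundary at c = 1.5, midway between the single-copy and
  multi-copy clusters, which is the convention of the multi-region
  lung-cancer literature this procedure descends from.  On synthetic
  cohorts at depth 150 this yields ≥ 95% early/late accuracy on gained
  regions versus ~75% for the continuous rule.
* **Clonal mutations on un-gained segments default to "early".**  The
  early+late grouping is intended to exhaust clonal mutations; a
  `strict_timing` switch marks them untimeable instead.  Mutations with
  no covering segment, or on homozygous deletions, are always
  untimeable and counted.

Per-gene early enrichment compares a gene's early ratio with ratios of
size-matched draws from all other timed mutations (≥ 1000 permutations,
one-sided (1+#≥obs)/(n+1) p-values, BH across tested genes, minimum 3
timed mutations per gene).

## Genome instability

Whole-genome doubling is called only when two methods agree: (1) the
major allele has copy number ≥ 2 over ≥ 50% of the covered genome
(length-weighted); (2) the length-weighted modal (major, minor) state
per chromosome arm has major ≥ 2 on ≥ 50% of arm length **and** ploidy
exceeds 2.5.  Method 2 is a deliberately simple surrogate for
published arm-level aberration-probability models, whose exact form is
not reproducible from their description; the conjunction with method 1
bounds its false positives.  wGII is the length-weighted fraction of
the genome whose **total** copy number differs from the rounded sample
ploidy (an `allele_aware` variant was considered and rejected as the
published definition speaks of "aberrant copy number compared to the
ploidy"); CIN = wGII > 0.2.  wGII is invariant to segment splitting,
which the suite property-checks.

Hypermutation: samples are ranked by TMB (nonsynonymous mutations per
Mb of exome, default 30 Mb) in descending order; the cutoff is the
largest successive difference within the top quartile of the ranking.
Restricting the search to the top quartile prevents a mid-distribution
gap from flagging the bulk of the cohort; with a zero maximal gap no
sample is flagged.

## Mutational signatures

Spectra use the 96 COSMIC-ordered pyrimidine-centred channels;
purine-reference SNVs are reverse-complemented.  Exposure fitting is
EM for a multinomial mixture (tolerance 1e-8 on the relative
log-likelihood, ≤ 10,000 iterations); the log-likelihood is
non-decreasing per iteration and exposure counts sum to the spectrum
total, both asserted in tests.  The presence rule — ≥ 10 mutations
(counts rounded half-up) and ≥ 5% of the sample total — matches the
rule used for reporting signatures in NMIBC cohorts.

De novo extraction replaces a hierarchical Dirichlet process sampler
with KL-NMF plus catalog matching: the cohort's signatures are
ultimately reported as catalog entities, and the HDP machinery is
orthogonal to that claim.  The NMF rank minimizes
AIC = 2·KL + 2·k·(95 + n<sub>samples</sub>).  A reconstruction-error
elbow and restart stability were evaluated first and rejected: for
multinomial count data each extra component absorbs sampling noise
with a roughly constant relative KL gain, and restart stability only
measures optimizer variance (every restart fits the same noise), so
neither stops at the true rank; the parameter-count penalty does, and
selects the correct rank on two-signature simulations.

The bundled signature catalog is **synthetic**: four stylized
96-channel vectors with the qualitative shapes of SBS2 (APOBEC C>T at
tCw), SBS5 (flat, clock-like), SBS13 (APOBEC C>G at tCw) and SBS22
(aristolochic-acid T>A, CTG-context peak), with low pairwise cosines
(≤ 0.3).  Real COSMIC v3.3 catalogs in the same TSV layout are read by
the same function; nothing downstream depends on the stand-in shapes
beyond separability.

APOBEC enrichment counts tCw and cytosine occurrences on both strands
of the ±20 nt reference windows around each mutated cytosine
(reference sequence, not sample consensus).  E = (mut_tCw/mut_C) /
(ctx_tCw/ctx_C); a one-sided Fisher test on the corresponding 2×2
table is BH-adjusted across samples; APOBEC load is
mut_tCw·max(0, (E−1)/E); samples split into none (q ≥ 0.05) and
low/high at the median load of the significant samples.

## Selection (dN/dS)

Opportunities come from enumerating all 3L single-base changes of each
in-frame CDS, weighted by a 12-parameter rate model (six
pyrimidine-centred substitution types × CpG flag) estimated from
synonymous sites or uniform.  This is a deliberate simplification of
full 192-rate covariate models: at the scale of the analyses here the
timing odds-ratio logic does not require covariate regression, and the
neutral calibration (global dN/dS within [0.9, 1.1] at 5,000
mutations; CI coverage ≥ 90%) validates the reduction.  dN/dS per
class is a rate ratio with an exact conditional-binomial CI
(conditioning on the total count, the class count is binomial); the
point-combined class pools missense, nonsense and splice.  Splice
opportunities are zero for plain CDS gene models, so splice mutations
contribute only where gene models annotate them; the synthetic data
contains none.  Timing odds ratios OR = ω_early/ω_late use the 2 / 0.5
phase cutoffs; ORs with an unstable stratum are not evaluable.

## Copy-number events and recurrence

Segments transform to log2(CN/ploidy) (CN 0 capped at 0.5); segments
with |log ratio| ≥ 0.25 qualify.  Adjacent qualifying segments merge
only when they share sign *and* total copy number — a nested
homozygous deletion inside a shallow arm loss therefore remains a
distinct focal event, mirroring amplitude-class separation in
GISTIC-style calling.  Merged spans are split at arm boundaries (a
whole-chromosome loss yields one event per arm) and each arm piece is
broad when it covers ≥ 0.75 of the arm.  Recurrence significance is a
G-like per-bin score (sum of |log ratio| over samples) against a null
that circularly rotates each sample's events along the concatenated
genome, preserving per-sample event counts and sizes exactly; outputs
are labelled GISTIC-like, and significant-locus lists are not expected
to match GISTIC2's peel-off peaks.

## Event dependency

The DISCOVER-style background (per-sample event loads respected) is
realized by curveball margin-preserving randomization: trades between
random row pairs, burn-in until ≥ 10× the number of ones have been
exchanged, thinning of 10 trades between the ≥ 1000 sampled matrices.
Row and column sums are asserted preserved on every run.  Pair
p-values are one-sided in each direction with BH within direction
(the direction-pooling convention is not standardized; within-direction
was chosen and is stated in the output).  Ordering interactions
between early and late strata use per-pair Fisher tests; infinite odds
ratios are reported as such alongside the Haldane–Anscombe corrected
value (+0.5 to every cell).  Type-I error of the pair test is
calibrated ≤ 1.5× nominal at α = 0.05 on independent Bernoulli
matrices (50 samples × 20 events, 200 replicates).

## Genomic subtyping

The binary event matrix unions ≥ 10%-frequency events (driver-gene
mutations restricted to the driver catalog, CNA events, signature
presence, wGD/CIN/hypermutation/APOBEC flags) with significant CNA
columns.  Brunet KL-NMF (multiplicative updates, tolerance 1e-6,
≤ 5,000 iterations, best of ≥ 30 restarts, objective non-increasing
per iteration) factorizes the matrix; samples take the argmax
coefficient, ties to the lowest factor.  Rank diagnostics run
consensus clustering over restarts and report the cophenetic
correlation per rank; the selected rank maximizes it (ties to the
smaller rank).

A structural caveat, discovered during validation and worth stating
plainly: when two subtypes are siblings — here the two FGFR3-driven
archetypes, which share their defining mutation and differ in the
chr9-deletion axis — merging them is as reproducible as splitting
them, so *every* consensus-stability statistic saturates (cophenetic
≥ 0.98 for all ranks) and rank selection between k and k−1 is
undetermined.  On matrices whose blocks lack such a hierarchy the
cophenetic criterion selects the true rank reliably (verified on
4-block matrices across seeds).  For cohorts with known archetype
structure the practical procedure is to inspect the emitted cophenetic
curve and fix the rank from the diagnostics; archetype recovery at the
known rank reaches mean ARI ≈ 0.94 on default synthetic cohorts.
Subtypes are characterized by one-vs-rest Fisher enrichment per event
(BH within event family), TMB rank-sum comparisons, and named
automatically by dominant hallmark (SBS22 → AA-like, wGD → GI,
9p+9q-del → FGFR3&chr9Del, FGFR3 → FGFR3/HRAS) with manual override.

## Expression scoring

Counts are normalized by median-of-ratios size factors.  Subtype gene
sets are the top 30 genes by BH-adjusted one-vs-rest rank-sum p, split
by the sign of a shrunken log2 fold change — a deliberate stand-in for
negative-binomial DE machinery, which is off-the-shelf and not a
contribution here; externally computed DE tables can be substituted.
Per-sample set scores are ssGSEA-style weighted KS running sums on
within-sample ranks (weight exponent 0.25), linearly rescaled to
[−1, 1] across the cohort; they are invariant to monotone within-sample
transforms, property-checked.  The subtype score is up-score minus
down-score (exactly antisymmetric under swapping the sets); survival
dichotomization uses the cohort median.

## Clinical statistics

The two-cohort comparison is the conventional two-sided Fisher exact
test (sum of hypergeometric probabilities ≤ the observed table's) with
step-up BH adjustment and an adjusted-p < 0.1 significance cutoff; the
suite verifies every row of the bundled published count table against
an independent full enumeration over tables with fixed margins, and BH
against statsmodels.  The printed adjusted values were evidently
computed from unrounded p (0.0579 prints as 0.058 where rounding first
would give 0.060); tests compare at two significant digits
accordingly.  Cox regression, Kaplan–Meier/log-rank and logistic
regression delegate to lifelines and statsmodels — they are plumbing,
not contributions — with multivariable Cox models rejected when any
covariate's variance inflation factor reaches 5.

## Integrative pathway analysis

Sixteen pathway sets ship as a fixture: ten canonical oncogenic
signaling pathways and six urothelial-cancer sets (histone
modification, SWI/SNF, DNA damage, cohesin, oxidative stress,
alternative splicing); the KMT2C/D- and ASXL1/2-style shorthand of the
printed lists is expanded to individual genes.  A gene is altered by a
driver mutation, a deep deletion (total CN 0 inside a deletion event)
or an amplification (log2 ratio ≥ 1 ≈ twice ploidy — numeric values
chosen here because the source defers to GISTIC2 without stating
them); a pathway is altered when any member is, so pathway fractions
are monotone under set growth.

## The synthetic cohort generator

The generator emulates the study conditions the analyses assume, with
full ground truth per mutation (CCF, clonality, multiplicity,
signature of origin, timing) and per sample (archetype, wGD, purity,
ploidy, exposures):

* **Toy genome**: 10 chromosomes (2 Mb total by default), p/q arms at
  40/60%, ~60 real-named 1.2 kb coding genes (CDKN2A on 9p, TSC1 on
  9q, FGFR3 on 4p, HRAS on 1p, TP53 on 7p); GC ≈ 0.4.
* **Four archetypes** with defaults mirroring the NMIBC genomic
  subtypes: AA-like (16 SNVs/Mb, SBS22-dominant — ≥ 5× the FGFR3/HRAS
  burden, so hypermutation and SBS22 presence co-occur), FGFR3/HRAS
  (2/Mb, flat 1+1 copy number, SBS5-dominant), FGFR3 & chr9Del (3/Mb,
  arm-level 9p+9q loss with a nested 9p21.3-like CDKN2A homozygous
  deletion — the hallmark focal event of the disease), and GI
  (5/Mb, tetraploid baseline with arm aberrations concentrated at
  recurrent hotspot arms including chr9, constrained to ≥ 25% aberrant
  genome since the archetype is CIN-positive by definition).  APOBEC
  (SBS2/13) weights rise across FGFR3/HRAS → chr9Del → GI, mirroring
  the reported APOBEC3B gradient.
* **Reads**: negative-binomial depth (mean 150, size 10 — WES
  overdispersion), binomial alt counts around
  VAF = m·ρ·CCF/(ρ·CN<sub>t</sub> + 2(1−ρ)); purity U(0.3, 0.9); one
  subclone per sample with CCF U(0.15, 0.6) and subclone fraction
  ~0.25 — enough to exercise clonality calls without a full subclonal
  architecture.  Variants with zero sampled alt reads are dropped, as
  a caller would.
* **Drivers**: archetype hotspot mutations at fixed CDS sites with
  matching annotations and concordant predictor verdicts; passenger
  missense variants receive mostly tolerated verdicts with 15%
  per-predictor discordance.
* **Expression**: negative-binomial counts (dispersion 0.3) over
  ~370 genes including the canonical marker panels; planted log2 fold
  changes tie p53/stroma/inflammation/claudin-low (and immune/
  interferon/BCG-response) panels to the AA-like and GI archetypes,
  plus 20 private filler markers per archetype for DE-recovery tests.
* **Outcomes**: exponential recurrence times with baseline hazard
  log(2)/24 per month (median RFS 24 months), log-HR log(2) for CIN
  plus archetype effects; uniform censoring on 4–73 months.

What the generator does **not** emulate — and hence what green tests
do not certify on real data: multifocal/multi-region sampling,
subclonal copy-number architecture, replication-timing and chromatin
covariates of mutation rate, indel signatures, germline contamination,
and panel-of-normals artifacts.  Archetype parameters are
order-of-magnitude choices exposed in `ArchetypeSpec`, not claims
about any specific cohort.

## Problem sizes

Default validation sizes were chosen so the full suite runs in a few
minutes on one CPU: 40-sample cohorts (10 per archetype) for recovery
tests; 100 replicates × 5,000 mutations for dN/dS calibration; 50
samples per class for wGD; 200 replicates of 50×20 matrices with 400
curveball draws for dependency type-I calibration; 10 seeds for
subtype recovery.  All are parameters, not limits.
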