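# Methods

This note documents the models and procedures implemented in `mammotype`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish
about real data.

## Expression preprocessing

Quantile normalization maps each sample's values onto the across-sample
mean of sorted columns. Ties within a sample receive the mean of the
reference quantiles they span. With tie-free columns the transform is
exactly idempotent (every column carries the reference distribution
afterwards); when tie patterns differ between samples, the tie-averaging
rule perturbs the per-column distributions slightly and exact idempotence
no longer holds. This is a property of the tie rule itself, not of the
implementation, and is why the idempotence property test draws continuous
matrices.

The variance filter removes probe rows whose sample standard deviation
(n − 1 denominator, as everywhere in the package) falls below a fraction
— default 0.028 — of the largest observed row SD. It runs at probe level,
before probe→gene collapse by arithmetic mean, matching the order in
which microarray pipelines describe these steps; the two orders differ
only for genes whose probes disagree strongly.

## Nearest-centroid subtyping

Each sample is assigned the subtype whose centroid maximizes the Spearman
correlation over the gene intersection of matrix and centroid set
(midranks for ties; configurable minimum-overlap floor, default 20
genes). Rank correlation makes the call invariant to any strictly
increasing per-sample transform of expression, so normalization scale
does not matter. Exact correlation ties are broken lexicographically by
subtype name and flagged; with continuous data they have probability
zero.

## Two-cluster significance (cluster-index Monte-Carlo test)

The statistic is the 2-cluster index CI — within-cluster sum of squares
about the cluster means divided by the total sum of squares about the
grand mean, samples as points in gene space. The null model is a single
multivariate Gaussian with diagonal covariance: the data covariance
eigenvalues (via SVD of the centered sample-by-gene matrix; at most
n − 1 are non-zero) with every eigenvalue floored at a background-noise
variance estimated as (MAD/0.6745)², the median absolute deviation taken
over all centered matrix entries. Each of `n_null` simulated datasets is
split by 2-means — an in-package vectorized Lloyd's algorithm, best of 10
seeded restarts — and p = (1 + #{CI_null ≤ CI_obs}) / (n_null + 1), so
the smallest attainable p is 1/(n_null + 1). This follows the logic of
cluster-significance testing à la SigClust; the covariance soft/hard
thresholding refinements of the original are deliberately omitted, which
makes the null slightly more conservative for strongly spiked covariance.
Calibration under a pure-noise null (rejection rate at α = 0.05 within
[0, 0.15] over 50 replicates) is checked by the test suite. The test is
honest only if the labels were produced by a procedure comparable to the
2-means split applied to the nulls; labels from the dendrogram's root cut
are close enough in practice (and conservative, since 2-means minimizes
CI directly).

Problem sizes in the suite and acceptance script (15–25 samples,
15–30 genes, n_null = 100 for calibration replicates and 500 for the
minimum-p check) were chosen as the smallest cohorts at which the
Monte-Carlo resolution is meaningful for the properties being checked.

## Signature Z-scores

A gene's standardized expression is (value − row mean)/row SD across the
scoring cohort; a sample's signature score is the mean over the
signature's genes present in the matrix. Genes missing from the matrix
are dropped, and zero-SD genes are excluded (they carry no ranking
information); both are reflected in `n_genes_used`. Scores are computed
over whatever sample set the caller supplies — including or excluding
normals is a cohort-definition decision left to the analysis, not the
function.

## Somatic variant filtering

A record is retained iff it passed the caller, alt-allele depth ≥ 10
(the "allele depth" rule is read as the alternate allele's depth, since
it is paired with an allele-frequency rule), VAF = alt/total ≥ 0.05, at
least one alt read on each strand, and its site is in neither the
matched-normal nor the known-SNP site set. The rules have no natural
order, but removal attribution needs one: removals are attributed to the
first failing rule in the fixed order pass → depth → VAF → strand →
normal → SNP, which guarantees retained + removals = input.

## Spectra, context enrichment, signature refitting

Catalogs count SNVs over the 96 classes (6 pyrimidine substitution types
× 4 × 4 flanks); purine-reference records are reverse-complemented onto
the pyrimidine strand together with their trinucleotide context, so a
variant set and its full reverse complement produce identical catalogs.

The flank-enrichment test compares, per tumor, the observed fraction of
mutations of a given pyrimidine whose 5′/3′ flank equals a stated base
against the genome's conditional flank proportion computed from a
32-context trinucleotide frequency table (e.g. freq(NTG)/freq(NTN) for
3′-G given T). Because the genome proportion is a single constant, a
two-sample rank-sum construction is not well defined; the per-tumor
differences are therefore tested with a one-sample Wilcoxon signed-rank
test, two-tailed. The genome table is an input (a helper in
`synthetic` generates synthetic backgrounds); computing it from a
reference FASTA is upstream of this package.

Refitting expresses a catalog, normalized to probabilities, as a
non-negative mixture of reference signatures with total weight ≤ 1. The
fit is greedy coordinate descent: at each step the single signature whose
1-D optimal (clipped) update most reduces the squared reconstruction
error is updated, until the relative SSE improvement drops below `tol`
(default 1e-3). Weights below `weight_cutoff` (default 0.06, the
conventional refitting cutoff) are then zeroed and the fit re-optimized
on the surviving signatures — re-fitting rather than rescaling, so the
reported weights are the best fit achievable with the reported support.
On three-signature problems the pre-cutoff fit lands within 5 % of (in
practice, at or below) a 0.01-resolution exhaustive grid search; this is
verified in the suite. Exome-to-genome context renormalization is not
applied by default; callers with exome catalogs and genome-derived
references can scale the catalog by a per-class vector before refitting.

No reference signature matrix is bundled: the refitter validates and
accepts any COSMIC-v2-layout table, and the synthetic module generates
sparse Dirichlet-drawn synthetic signature matrices for testing.

## CNA characterization

Gene status is the 5-level code (−2 homozygous deletion … +2 multi-copy
amplification). Driver calls intersect aberrant statuses with census
alteration types; because it is genuinely open which levels should count
as a driver event, the default counts any gain/loss (±1) and a strict
mode (±2) is exposed — relaxing the threshold can only add calls
(monotonicity is property-tested). Profile similarity reports both the
identical-status fraction over the shared gene universe and the Jaccard
index of aberrant gene sets; pairs are ranked by the former, which is
what surfaces near-duplicate profiles.

## Exact statistics

Fisher's two-sided p sums hypergeometric probabilities of all
same-margin tables whose probability does not exceed the observed
table's, with a relative tolerance of 1e-7 guarding floating-point
equality at the boundary. This is the convention under which the cohort's
printed association p-values (0.009, 0.13, 0.08) reproduce exactly; a
mid-p variant would not. Rank-sum tests use exact enumeration for
combined n ≤ 25 with no ties and the continuity-corrected normal
approximation with midranks and tie correction otherwise; signed-rank
tests drop zeros (counting them) and are exact up to 20 non-zero
tie-free differences. No multiple-testing correction is applied anywhere
by default — the analyses report unadjusted p-values — but a
Benjamini–Hochberg helper is available.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the study-shaped conditions: 18 tumors in 9
subtypes (2 each), 589 mutations per tumor (the cohort mean), sequencing
depth Poisson around 58×, CNA event rate 0.065 (≈1300 aberrant genes out
of 20k at genome scale) with 65 % of events being gains, and a planted
near-identical CNA pair. Expression is centroid-plus-i.i.d.-Gaussian
noise with block-structured centroids (an N(0,1) draw per gene plus a
+2.5 shift on the subtype's own block), the simplest model under which
rank-correlation subtyping is consistent and centroid distinctness
(pairwise |ρ| < 0.9) holds by construction; `noise_sd` defaults to 0.5,
comfortably inside the regime where recovery is near-perfect, and tests
vary it. One global seed drives all generators through independently
spawned streams, so outputs are byte-identical across runs and drawing
one artifact never perturbs another.

What passing on synthetic cohorts does *not* show: real microarray data
have correlated gene noise, batch effects and probe-level artifacts that
i.i.d. Gaussian noise cannot produce; real mutational spectra include
indels (catalogs here are SNV-only, with non-SNVs counted separately) and
sequencing-context biases; real CNA profiles are segmental, not
gene-i.i.d. The synthetic results validate the correctness of the
operations and the internal consistency of the pipeline, not its
robustness to those real-data pathologies.

## Numerical conventions and degenerate inputs

Sample SD uses n − 1 throughout. Spearman uses midranks. Degenerate
inputs fail loudly with typed errors (empty groups, all-zero catalogs,
all-constant signatures, disjoint CNA gene universes) except where a
degenerate answer is well defined: identical pooled samples give p = 1,
all-zero signed-rank differences give p = 1 with a warning, an
all-neutral CNA profile has burden 0 with undefined amplified fraction
(NaN).
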